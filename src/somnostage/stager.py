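"""Two-step sleep-stage classifier: attention-LSTM cascade.

Stage scoring is hierarchical.  A first attention-augmented LSTM network
separates Wake / REM / NREM (the WRN task); a second network with the
same architecture refines NREM into N1 / N2 / N3; the cascade splices
the sub-stage predictions back into the WRN output to produce the final
five-class hypnogram.  Each network is: 128-unit LSTM (L2-regularised)
→ batch normalisation → additive temporal attention → 64-unit LSTM
(L2-regularised) → batch normalisation → dropout 0.3 → 64-unit dense
ReLU → dropout 0.2 → softmax.  Training minimises weighted categorical
cross-entropy with AdamW (lr 5·10⁻⁴, weight decay 10⁻⁴), class weights
inverse to class frequency with the REM class further up-weighted.

The module follows a model/results pattern: :class:`TwoStepStager` is
built from a time-ordered feature matrix and stage labels, ``fit()``
trains both networks on a stratified 80/20 split (with optional
stratified k-fold cross-validation inside the training split) and
returns a :class:`StagingResults` carrying the held-out metrics,
confusion matrix and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .evaluation import classification_report, confusion_matrix
from .io import STAGES

__all__ = [
    "StageMaps",
    "AttentionLstmConfig",
    "SequenceDataset",
    "build_sequences",
    "compute_class_weights",
    "AttentionLstmClassifier",
    "TwoStepStager",
    "StagingResults",
    "cascade_predict",
]


@dataclass(frozen=True)
class StageMaps:
    """Label maps of the two-step hierarchy."""

    five_class: tuple = STAGES
    wrn: dict = field(default_factory=lambda: {
        "W": "W", "REM": "R", "N1": "NREM", "N2": "NREM", "N3": "NREM",
    })
    nrem: tuple = ("N1", "N2", "N3")

    @property
    def wrn_classes(self) -> tuple:
        return ("W", "R", "NREM")


@dataclass
class AttentionLstmConfig:
    """Architecture and training hyper-parameters."""

    lstm1_units: int = 128
    lstm2_units: int = 64
    dense_units: int = 64
    dropout1: float = 0.3
    dropout2: float = 0.2
    l2_coeff: float = 1e-4
    lr: float = 5e-4
    weight_decay: float = 1e-4
    epochs: int = 50
    batch_size: int = 128
    rem_boost: float = 1.5
    timesteps: int = 6

    def __post_init__(self) -> None:
        if not (0 <= self.dropout1 < 1 and 0 <= self.dropout2 < 1):
            raise ValueError("dropout rates must lie in [0, 1)")
        for name in ("lstm1_units", "lstm2_units", "dense_units",
                     "epochs", "batch_size", "timesteps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SequenceDataset:
    """Sequence samples of shape (n, timesteps, features) with one-hot labels."""

    inputs: np.ndarray
    onehot: np.ndarray
    class_names: tuple
    labels: np.ndarray          # string labels, length n
    segment_indices: np.ndarray

    def __post_init__(self) -> None:
        if self.inputs.ndim != 3:
            raise ValueError("inputs must be (n, timesteps, features)")
        if not np.all(np.isfinite(self.inputs)):
            raise ValueError("non-finite entries in sequence inputs")
        if self.onehot.size and not np.allclose(self.onehot.sum(axis=1), 1.0):
            raise ValueError("one-hot rows must sum to 1")

    def __len__(self) -> int:
        return self.inputs.shape[0]


def _onehot(labels: np.ndarray, classes: tuple) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)))
    for r, lab in enumerate(labels):
        out[r, idx[lab]] = 1.0
    return out


def build_sequences(
    F: np.ndarray,
    labels,
    timesteps: int = 6,
    groups=None,
    class_names: tuple = STAGES,
) -> SequenceDataset:
    """Turn a time-ordered feature matrix into sliding sequence samples.

    Sample i contains the feature vectors of windows [i−T+1 … i] and the
    label of window i.  Sequences never span recording boundaries
    (``groups`` marks the recording of each row); the first T−1 windows
    of each recording are left-padded by repeating the earliest vector.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[0] == 0:
        raise ValueError("feature matrix must be non-empty and 2-D")
    labels = np.asarray(labels)
    n = F.shape[0]
    if groups is None:
        groups = np.zeros(n)
    groups = np.asarray(groups)

    seqs = np.empty((n, timesteps, F.shape[1]))
    for g in np.unique(groups):
        rows = np.nonzero(groups == g)[0]
        block = F[rows]
        for j in range(rows.size):
            lo = max(0, j - timesteps + 1)
            window = block[lo : j + 1]
            if window.shape[0] < timesteps:
                pad = np.repeat(window[:1], timesteps - window.shape[0], axis=0)
                window = np.vstack([pad, window])
            seqs[rows[j]] = window
    return SequenceDataset(
        inputs=seqs,
        onehot=_onehot(labels, class_names),
        class_names=tuple(class_names),
        labels=labels,
        segment_indices=np.arange(n),
    )


def compute_class_weights(
    labels, classes: tuple, rem_boost: float = 1.5, boost_class: str = "R"
) -> dict:
    """Balanced inverse-frequency weights, REM further up-weighted.

    ``w_c = n_total / (k · n_c)``; the weight of ``boost_class`` is then
    multiplied by ``rem_boost``.  Every class must be present.
    """
    labels = np.asarray(labels)
    k = len(classes)
    weights = {}
    for c in classes:
        n_c = int(np.sum(labels == c))
        if n_c == 0:
            raise ValueError(f"class {c!r} absent from labels")
        weights[c] = labels.size / (k * n_c)
    if boost_class in weights:
        weights[boost_class] *= rem_boost
    return weights


class AttentionLstmClassifier:
    """One attention-augmented LSTM network (three-class by default)."""

    def __init__(self, n_features: int, n_classes: int,
                 cfg: AttentionLstmConfig, seed: int = 0):
        self.cfg = cfg
        self.n_features = n_features
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        self.lstm1 = nn.LstmLayer(n_features, cfg.lstm1_units, rng)
        self.bn1 = nn.BatchNorm(cfg.lstm1_units)
        self.attention = nn.TemporalAttention(cfg.lstm1_units, rng)
        self.lstm2 = nn.LstmLayer(cfg.lstm1_units, cfg.lstm2_units, rng)
        self.bn2 = nn.BatchNorm(cfg.lstm2_units)
        self.dense1 = nn.Dense(cfg.lstm2_units, cfg.dense_units, rng)
        self.dense_out = nn.Dense(cfg.dense_units, n_classes, rng)
        self._drop_rng = np.random.default_rng(seed + 1)

    @property
    def params(self) -> list:
        out = []
        for layer in (self.lstm1, self.bn1, self.attention, self.lstm2,
                      self.bn2, self.dense1, self.dense_out):
            out.extend(layer.params)
        return out

    @property
    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def forward(self, X: np.ndarray, train: bool = False) -> nn.Tensor:
        """Logits for a batch X of shape (B, T, F)."""
        T = X.shape[1]
        xs = [nn.Tensor(X[:, t, :], requires_grad=False) for t in range(T)]
        hs = self.lstm1.forward(xs)
        hs = self.bn1.forward_seq(hs, train)
        hs, self.last_attention = self.attention.forward(hs)
        hs2 = self.lstm2.forward(hs)
        h = self.bn2.forward(hs2[-1], train)
        h = nn.dropout_mask(h, self.cfg.dropout1, self._drop_rng, train)
        h = nn.relu(self.dense1.forward(h))
        h = nn.dropout_mask(h, self.cfg.dropout2, self._drop_rng, train)
        return self.dense_out.forward(h)

    def state_dict(self) -> dict:
        """All learnable arrays and batch-norm running statistics, by name."""
        out = {}
        layers = {
            "lstm1": self.lstm1, "bn1": self.bn1, "att": self.attention,
            "lstm2": self.lstm2, "bn2": self.bn2, "dense1": self.dense1,
            "out": self.dense_out,
        }
        for lname, layer in layers.items():
            for pname in ("W", "U", "b", "v", "gamma", "beta"):
                if hasattr(layer, pname):
                    out[f"{lname}.{pname}"] = getattr(layer, pname).data
            if isinstance(layer, nn.BatchNorm):
                out[f"{lname}.running_mean"] = layer.running_mean
                out[f"{lname}.running_var"] = layer.running_var
        return out

    def load_state_dict(self, state: dict) -> None:
        layers = {
            "lstm1": self.lstm1, "bn1": self.bn1, "att": self.attention,
            "lstm2": self.lstm2, "bn2": self.bn2, "dense1": self.dense1,
            "out": self.dense_out,
        }
        for key, arr in state.items():
            lname, pname = key.split(".")
            layer = layers[lname]
            if pname in ("running_mean", "running_var"):
                setattr(layer, pname, np.asarray(arr, dtype=float))
            else:
                getattr(layer, pname).data = np.asarray(arr, dtype=float)

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        probs = []
        for i in range(0, X.shape[0], batch_size):
            logits = self.forward(X[i : i + batch_size], train=False).data
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            probs.append(e / e.sum(axis=1, keepdims=True))
        return np.vstack(probs)

    def fit(self, X: np.ndarray, y_onehot: np.ndarray,
            class_weights: np.ndarray, seed: int = 0,
            epochs: int | None = None, verbose: bool = False) -> list:
        """Train with AdamW on shuffled mini-batches; returns per-epoch losses."""
        cfg = self.cfg
        epochs = cfg.epochs if epochs is None else epochs
        opt = nn.AdamW(self.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
        rng = np.random.default_rng(seed)
        n = X.shape[0]
        sample_w = y_onehot @ class_weights
        l2_params = self.lstm1.kernels + self.lstm2.kernels
        history = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for i in range(0, n, cfg.batch_size):
                idx = order[i : i + cfg.batch_size]
                opt.zero_grad()
                logits = self.forward(X[idx], train=True)
                loss = nn.weighted_softmax_xent(
                    logits, y_onehot[idx], sample_w[idx]
                )
                if cfg.l2_coeff > 0:
                    for p in l2_params:
                        loss = nn.add(loss, nn.scale(nn.sum_all(nn.square(p)),
                                                     cfg.l2_coeff))
                loss.backward()
                opt.step()
                total += float(loss.data) * idx.size
            history.append(total / n)
            if verbose:
                print(f"epoch {epoch + 1}/{epochs}  loss {history[-1]:.4f}")
        return history


def cascade_predict(stager: "TwoStepStager", X: np.ndarray) -> np.ndarray:
    """Five-class labels from the fitted cascade.

    The WRN network labels every sample; W and R are final, NREM samples
    are routed (index-aligned) to the sub-stage network and its
    N1/N2/N3 output is spliced back into position.
    """
    if stager.model_wrn is None or stager.model_nrem is None:
        raise ValueError("stager is not fitted")
    maps = stager.maps
    p1 = stager.model_wrn.predict_proba(X)
    wrn = np.array(maps.wrn_classes)[np.argmax(p1, axis=1)]
    out = wrn.astype(object)
    nrem_idx = np.nonzero(wrn == "NREM")[0]
    if nrem_idx.size:
        p2 = stager.model_nrem.predict_proba(X[nrem_idx])
        sub = np.array(maps.nrem)[np.argmax(p2, axis=1)]
        if sub.size != nrem_idx.size:  # sample-mismatch guard
            raise RuntimeError(
                f"cascade misalignment: {nrem_idx.size} NREM samples, "
                f"{sub.size} sub-stage predictions"
            )
        out[nrem_idx] = sub
    final = np.array([x if x != "R" else "REM" for x in out])
    if not set(final) <= set(STAGES):
        raise RuntimeError(f"cascade produced labels outside {STAGES}")
    return final


class TwoStepStager:
    """Hierarchical five-class sleep stager (model object).

    Parameters
    ----------
    features : ndarray (n_windows, n_features)
        Time-ordered feature rows (e.g. principal-component scores),
        ordered within each recording.
    labels : sequence of str
        Five-class stage label per window.
    groups : sequence, optional
        Recording id per window; sequences never cross recordings.
    config : AttentionLstmConfig
    scale_features : bool
        Z-score features on the training split before sequence building.
    """

    def __init__(self, features, labels, groups=None,
                 config: AttentionLstmConfig | None = None,
                 maps: StageMaps | None = None,
                 scale_features: bool = True,
                 feature_names=None):
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels)
        if self.features.shape[0] != self.labels.size:
            raise ValueError("features and labels disagree in length")
        present = set(np.unique(self.labels))
        missing = set(STAGES) - present
        if missing:
            raise ValueError(f"stages absent from training labels: {sorted(missing)}")
        self.groups = (np.zeros(self.labels.size) if groups is None
                       else np.asarray(groups))
        self.config = config or AttentionLstmConfig()
        self.maps = maps or StageMaps()
        self.scale_features = scale_features
        self.feature_names = feature_names
        self.model_wrn: AttentionLstmClassifier | None = None
        self.model_nrem: AttentionLstmClassifier | None = None
        self.scaler_mean_: np.ndarray | None = None
        self.scaler_std_: np.ndarray | None = None

    # -- helpers -----------------------------------------------------------

    def _scaled(self, F: np.ndarray) -> np.ndarray:
        if not self.scale_features:
            return F
        return (F - self.scaler_mean_) / self.scaler_std_

    def _fit_scaler(self, F: np.ndarray) -> None:
        if self.scale_features:
            self.scaler_mean_ = F.mean(axis=0)
            std = F.std(axis=0, ddof=1)
            std[std == 0] = 1.0
            self.scaler_std_ = std
        else:
            self.scaler_mean_ = np.zeros(F.shape[1])
            self.scaler_std_ = np.ones(F.shape[1])

    def _train_pair(self, X, labels5, seed: int, epochs: int | None):
        cfg = self.config
        maps = self.maps
        wrn_labels = np.array([maps.wrn[l] for l in labels5])
        w1 = compute_class_weights(wrn_labels, maps.wrn_classes,
                                   rem_boost=cfg.rem_boost, boost_class="R")
        m1 = AttentionLstmClassifier(X.shape[2], 3, cfg, seed=seed)
        m1.fit(X, _onehot(wrn_labels, maps.wrn_classes),
               np.array([w1[c] for c in maps.wrn_classes]),
               seed=seed, epochs=epochs)

        # stage 2 trains on ground-truth NREM windows only
        nrem_mask = wrn_labels == "NREM"
        w2 = compute_class_weights(labels5[nrem_mask], maps.nrem,
                                   rem_boost=1.0)
        m2 = AttentionLstmClassifier(X.shape[2], 3, cfg, seed=seed + 1)
        m2.fit(X[nrem_mask], _onehot(labels5[nrem_mask], maps.nrem),
               np.array([w2[c] for c in maps.nrem]),
               seed=seed + 1, epochs=epochs)
        return m1, m2

    # -- estimation --------------------------------------------------------

    def fit(self, seed: int = 0, epochs: int | None = None,
            test_fraction: float = 0.2, cv_folds: int = 0) -> "StagingResults":
        """Train the cascade; returns results on the held-out test split.

        The data are split 80/20 stratified on the five-class label
        (deterministic given ``seed``).  With ``cv_folds`` > 0, a
        stratified k-fold cross-validation inside the training split
        estimates accuracy variability before the final models are
        trained on the full training split.
        """
        n = self.features.shape[0]
        idx = np.arange(n)
        tr, te = train_test_split(
            idx, test_size=test_fraction, stratify=self.labels,
            random_state=seed,
        )
        tr, te = np.sort(tr), np.sort(te)
        self._fit_scaler(self.features[tr])
        dataset = build_sequences(
            self._scaled(self.features), self.labels,
            timesteps=self.config.timesteps, groups=self.groups,
        )
        X, y5 = dataset.inputs, dataset.labels

        cv_scores = []
        if cv_folds and cv_folds > 1:
            skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                                  random_state=seed)
            for k, (cv_tr, cv_va) in enumerate(skf.split(tr, y5[tr])):
                m1, m2 = self._train_pair(X[tr[cv_tr]], y5[tr[cv_tr]],
                                          seed=seed + 100 + k, epochs=epochs)
                holder = replace_models(self, m1, m2)
                pred = cascade_predict(holder, X[tr[cv_va]])
                cv_scores.append(float(np.mean(pred == y5[tr[cv_va]])))

        self.model_wrn, self.model_nrem = self._train_pair(
            X[tr], y5[tr], seed=seed, epochs=epochs,
        )
        y_pred = cascade_predict(self, X[te])
        cm = confusion_matrix(y5[te], y_pred, classes=list(STAGES))
        report = classification_report(cm)
        return StagingResults(
            model=self, train_idx=tr, test_idx=te,
            y_true=y5[te], y_pred=y_pred,
            confusion=cm, report=report, cv_scores=cv_scores,
            seed=seed,
        )

    def predict(self, features, groups=None) -> np.ndarray:
        """Five-class labels for new, time-ordered feature rows."""
        if self.model_wrn is None:
            raise ValueError("call fit() first")
        F = np.asarray(features, dtype=float)
        ds = build_sequences(
            self._scaled(F), np.array(["W"] * F.shape[0]),
            timesteps=self.config.timesteps, groups=groups,
        )
        return cascade_predict(self, ds.inputs)

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        """Write both networks, the scaler and the config to a directory."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        if self.model_wrn is None:
            raise ValueError("cannot save an unfitted stager")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "model_wrn.npz", **self.model_wrn.state_dict())
        np.savez(directory / "model_nrem.npz", **self.model_nrem.state_dict())
        np.savez(directory / "scaler.npz",
                 mean=self.scaler_mean_, std=self.scaler_std_)
        meta = {
            "config": asdict(self.config),
            "n_features": int(self.features.shape[1]),
            "scale_features": self.scale_features,
            "feature_names": list(self.feature_names or []),
        }
        (directory / "stager.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "TwoStepStager":
        """Rebuild a fitted stager saved with :meth:`save`."""
        import json
        from pathlib import Path

        directory = Path(directory)
        meta = json.loads((directory / "stager.json").read_text())
        cfg = AttentionLstmConfig(**meta["config"])
        n_feat = meta["n_features"]
        # placeholder training data: one window per stage keeps the
        # constructor's completeness check satisfied
        stub = np.zeros((len(STAGES), n_feat))
        obj = cls(stub, np.array(STAGES), config=cfg,
                  scale_features=meta["scale_features"],
                  feature_names=meta["feature_names"] or None)
        obj.model_wrn = AttentionLstmClassifier(n_feat, 3, cfg, seed=0)
        obj.model_wrn.load_state_dict(dict(np.load(directory / "model_wrn.npz")))
        obj.model_nrem = AttentionLstmClassifier(n_feat, 3, cfg, seed=0)
        obj.model_nrem.load_state_dict(dict(np.load(directory / "model_nrem.npz")))
        sc = np.load(directory / "scaler.npz")
        obj.scaler_mean_, obj.scaler_std_ = sc["mean"], sc["std"]
        return obj


def replace_models(stager: TwoStepStager, m1, m2) -> TwoStepStager:
    """Shallow copy of a stager with substituted networks (CV plumbing)."""
    import copy

    out = copy.copy(stager)
    out.model_wrn, out.model_nrem = m1, m2
    return out


@dataclass
class StagingResults:
    """Held-out evaluation of a fitted :class:`TwoStepStager`."""

    model: TwoStepStager
    train_idx: np.ndarray
    test_idx: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    confusion: "object"
    report: "object"
    cv_scores: list
    seed: int

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    def summary(self) -> str:
        """Plain-text classification report for the held-out test split."""
        lines = [
            "Two-step attention-LSTM sleep stager",
            f"  windows: {self.model.features.shape[0]}  "
            f"features: {self.model.features.shape[1]}  "
            f"timesteps: {self.model.config.timesteps}",
            f"  train/test: {self.train_idx.size}/{self.test_idx.size}  "
            f"seed: {self.seed}",
        ]
        if self.cv_scores:
            lines.append(
                f"  CV accuracy: {np.mean(self.cv_scores):.3f} "
                f"± {np.std(self.cv_scores):.3f} ({len(self.cv_scores)} folds)"
            )
        lines.append("")
        lines.append(self.report.to_text())
        return "\n".join(lines)
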