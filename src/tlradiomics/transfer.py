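"""Adaptive cross-domain transfer training.

The model has three parts:

1. a **source network** pretrained on labelled source-domain images,
   which defines an intermediate feature space;
2. a **target network** of the same backbone family, trained on the CT
   patches under a feature-matching constraint;
3. a **source-domain feature-selection network** made of two small
   meta-networks: meta-net A produces per-channel gates ``g`` in [0, 1]
   scoring how useful each source channel is for the target task, and
   meta-net B provides per-stage linear maps ``M`` aligning target-stage
   features with the source-stage feature space.

The constraint added to the target task loss is

    lambda * sum_stages (1 / C) * sum_c g_c * ||(M t)_c - s_c||^2 / P

(``C`` channels, ``P`` spatial positions, batch-averaged), i.e. the
target is pulled toward the source representation only along gated
channels.  Gates are trained against the validation cohort: a logistic
probe predicts validation labels from gated, pooled source features, and
an L1 penalty on the gates prices in redundancy, so channels that do not
help the target task see their gates fall.  With a mismatched source
this drives the constraint toward zero, mitigating negative transfer.

Feature extraction concatenates globally average-pooled activations of
every stage; under the default stage widths [64, 128, 256, 512, 1024,
1920] this yields exactly 3904 features per patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import (
    DataError,
    LeakageError,
    NumericError,
    ParameterError,
    ShapeError,
)
from .nn import Adam, StageConvNet, sigmoid, softmax_cross_entropy
from .preprocessing import CtPatch
from .signature import FeatureMatrix

__all__ = [
    "NetworkConfig",
    "MetaSelectionState",
    "TrainHistory",
    "SourceModel",
    "TargetModel",
    "pretrain_source",
    "selection_gates",
    "transfer_constraint_loss",
    "train_target_with_transfer",
    "train_nontransfer",
    "MetaProbe",
    "extract_features",
    "filter_response_heatmap",
    "patches_to_array",
]

DEFAULT_STAGE_CHANNELS = (64, 128, 256, 512, 1024, 1920)


@dataclass(frozen=True)
class NetworkConfig:
    """Backbone configuration.

    ``width_scale`` shrinks every stage width for desk-scale runs; the
    default widths sum to 3904, the feature-vector length of the full
    model.
    """

    stage_channels: tuple = DEFAULT_STAGE_CHANNELS
    input_size: int = 224
    n_source_classes: int = 2
    n_target_classes: int = 2
    width_scale: float = 1.0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.stage_channels):
            raise ParameterError("all stage channels must be > 0")
        if not (0 < self.width_scale <= 1):
            raise ParameterError("width_scale must be in (0, 1]")
        if self.input_size < 32:
            raise ParameterError("input_size must be >= 32")

    @property
    def scaled_channels(self) -> list[int]:
        return [max(1, int(round(c * self.width_scale))) for c in self.stage_channels]

    @property
    def feature_width(self) -> int:
        return sum(self.scaled_channels)


@dataclass
class MetaSelectionState:
    """Parameters of the two meta-networks plus the constraint weight.

    ``gate_bias``/``gate_slope`` parameterise meta-net A: the gate of
    source channel ``c`` at stage ``s`` is
    ``sigmoid(gate_bias[s][c] + gate_slope[s][c] * pooled_c)``; all-zero
    parameters give gates of exactly 0.5.  ``matching`` holds meta-net
    B's per-stage square maps (initialised to identity).
    """

    gate_bias: list
    gate_slope: list
    matching: list
    lam: float = 1.0

    @classmethod
    def init(cls, channels: list[int], lam: float = 1.0) -> "MetaSelectionState":
        if lam < 0:
            raise ParameterError("lambda must be >= 0")
        return cls(
            gate_bias=[np.zeros(c) for c in channels],
            gate_slope=[np.zeros(c) for c in channels],
            matching=[np.eye(c) for c in channels],
            lam=float(lam),
        )

    def gates(self, pooled_source: list[np.ndarray]) -> list[np.ndarray]:
        return selection_gates(self, pooled_source)


def selection_gates(
    state: MetaSelectionState, source_stage_features: list[np.ndarray]
) -> list[np.ndarray]:
    """Per-stage gates in [0, 1]^C from pooled source-stage features.

    ``source_stage_features[s]`` is (N, C_s) (globally average-pooled);
    the batch mean enters the gate pre-activation, so one gate vector is
    produced per stage.
    """
    gates = []
    for s, feats in enumerate(source_stage_features):
        feats = np.atleast_2d(np.asarray(feats, dtype=np.float64))
        if feats.shape[1] != state.gate_bias[s].shape[0]:
            raise ShapeError(
                f"stage {s}: {feats.shape[1]} channels vs "
                f"{state.gate_bias[s].shape[0]} meta-parameters"
            )
        pooled = feats.mean(axis=0)
        gates.append(sigmoid(state.gate_bias[s] + state.gate_slope[s] * pooled))
    return gates


def transfer_constraint_loss(
    target_feats: list[np.ndarray],
    source_feats: list[np.ndarray],
    state: MetaSelectionState,
    gates: list[np.ndarray] | None = None,
) -> float:
    """Gated feature-matching loss.

    Per stage: ``(1/C) * sum_c g_c * mean_sq_c`` where ``mean_sq_c`` is the
    per-channel (and per-sample) mean squared difference between linearly
    matched target features ``M t`` and source features ``s``; stages are
    summed and the whole is scaled by ``lambda``.
    """
    if state.lam == 0:
        return 0.0
    total = 0.0
    for s, (t, src) in enumerate(zip(target_feats, source_feats)):
        t = np.asarray(t, dtype=np.float64)
        src = np.asarray(src, dtype=np.float64)
        if not (np.isfinite(t).all() and np.isfinite(src).all()):
            raise NumericError("non-finite stage features")
        if t.ndim == 3:  # single sample (C,H,W)
            t, src = t[None], src[None]
        n, c = t.shape[0], t.shape[1]
        p = t.shape[2] * t.shape[3]
        m = state.matching[s]
        mt = np.einsum("dc,nchw->ndhw", m, t)
        diff = mt - src
        g = gates[s] if gates is not None else np.full(c, 1.0)
        msd = (diff**2).sum(axis=(0, 2, 3)) / (n * p)
        total += float((g * msd).sum() / c)
    return state.lam * total


def _constraint_grads(t_stages, s_stages, state, gates):
    """Gradients of the constraint w.r.t. target stage activations and M."""
    stage_grads, m_grads, loss = [], [], 0.0
    for s, (t, src) in enumerate(zip(t_stages, s_stages)):
        n, c = t.shape[0], t.shape[1]
        p = t.shape[2] * t.shape[3]
        m = state.matching[s]
        g = gates[s]
        mt = np.einsum("dc,nchw->ndhw", m, t)
        diff = mt - src
        msd = (diff**2).sum(axis=(0, 2, 3)) / (n * p)
        loss += float((g * msd).sum() / c)
        scale = 2.0 * state.lam / (n * p * c)
        wdiff = g[None, :, None, None] * diff
        stage_grads.append(scale * np.einsum("dc,ndhw->nchw", m, wdiff))
        m_grads.append(scale * np.einsum("ndhw,nchw->dc", wdiff, t))
    return state.lam * loss, stage_grads, m_grads


@dataclass
class TrainHistory:
    """Per-epoch record of a training run."""

    task_loss: list = field(default_factory=list)
    constraint_loss: list = field(default_factory=list)
    val_auc: list = field(default_factory=list)
    seed: int = 0
    config: dict = field(default_factory=dict)

    def validate(self) -> None:
        n = len(self.task_loss)
        if len(self.constraint_loss) != n or len(self.val_auc) != n:
            raise ShapeError("history lists must have equal length")
        if not all(np.isfinite(self.task_loss)) or not all(
            np.isfinite(self.constraint_loss)
        ):
            raise NumericError("recorded losses must be finite")


@dataclass
class SourceModel:
    net: StageConvNet
    cfg: NetworkConfig
    seed: int
    history: TrainHistory


@dataclass
class TargetModel:
    net: StageConvNet
    cfg: NetworkConfig
    seed: int
    history: TrainHistory
    meta: MetaSelectionState | None = None


def patches_to_array(patches) -> np.ndarray:
    """Stack patches (CtPatch or (H,W,3) arrays) into (N, 3, H, W)."""
    arrs = []
    for p in patches:
        px = p.pixels if isinstance(p, CtPatch) else np.asarray(p, dtype=np.float64)
        arrs.append(px.transpose(2, 0, 1))
    return np.stack(arrs, axis=0)


def _check_classes(labels: np.ndarray, minimum_per_class: int = 1) -> None:
    vals, counts = np.unique(labels, return_counts=True)
    if len(vals) < 2:
        raise DataError("need at least two classes")
    if counts.min() < minimum_per_class:
        raise DataError(f"need >= {minimum_per_class} images per class")


def _auc(scores, labels) -> float:
    from .evaluation import auc

    try:
        return auc(scores, labels)
    except DataError:
        return float("nan")


# ---------------------------------------------------------------------------
# training


def pretrain_source(
    source_images,
    source_labels,
    cfg: NetworkConfig,
    seed: int,
    epochs: int = 12,
    batch_size: int = 32,
    lr: float = 1e-3,
) -> SourceModel:
    """Train the source network on labelled source-domain images.

    ``source_images`` is (N, H, W, 3) in [0, 1] (or a fixtures
    ``SourceDomain``).  Zero epochs returns the seeded initialisation.
    """
    if hasattr(source_images, "images"):  # SourceDomain
        source_labels = source_images.labels
        source_images = source_images.images
    x = np.asarray(source_images, dtype=np.float64).transpose(0, 3, 1, 2)
    y = np.asarray(source_labels, dtype=np.int64)
    _check_classes(y, minimum_per_class=4)

    rng = np.random.default_rng(seed)
    net = StageConvNet(cfg.scaled_channels, int(y.max()) + 1, rng)
    opt = Adam(lr=lr)
    shuffle_rng = np.random.default_rng(seed + 1)
    hist = TrainHistory(seed=seed, config=asdict(cfg))
    for _ in range(epochs):
        order = shuffle_rng.permutation(len(x))
        losses = []
        for b0 in range(0, len(x), batch_size):
            idx = order[b0 : b0 + batch_size]
            logits, _ = net.forward(x[idx])
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            grads = net.backward(dlogits)
            opt.step(net.params, grads)
            losses.append(loss)
        hist.task_loss.append(float(np.mean(losses)))
        hist.constraint_loss.append(0.0)
        hist.val_auc.append(float("nan"))
    return SourceModel(net=net, cfg=cfg, seed=seed, history=hist)


class MetaProbe:
    """Validation-driven gate learner (meta-net A trainer).

    A logistic probe predicts validation labels from gated, pooled source
    features; its loss plus an L1 gate penalty is minimised jointly over
    the probe weights and the gate parameters.
    """

    def __init__(self, state: MetaSelectionState, n_features: int,
                 rho: float = 0.05, lr: float = 0.05):
        self.state = state
        self.w = np.zeros(n_features)
        self.b = 0.0
        self.rho = rho
        self.opt = Adam(lr=lr)

    def update(self, pooled_val: list[np.ndarray], y_val: np.ndarray,
               steps: int = 25) -> None:
        f = np.concatenate(pooled_val, axis=1)  # (N, F)
        mu, sd = f.mean(axis=0), f.std(axis=0)
        sd[sd == 0] = 1.0
        f = (f - mu) / sd
        pooled_means = [p.mean(axis=0) for p in pooled_val]
        sizes = [p.shape[1] for p in pooled_val]
        n, nf = f.shape
        for _ in range(steps):
            zs = [
                self.state.gate_bias[s] + self.state.gate_slope[s] * pooled_means[s]
                for s in range(len(sizes))
            ]
            g = np.concatenate([sigmoid(z) for z in zs])
            fg = f * g
            p = sigmoid(fg @ self.w + self.b)
            dz = (p - y_val) / n
            dw = fg.T @ dz + 1e-3 * self.w
            db = float(dz.sum())
            dg = (f.T @ dz) * self.w + self.rho / nf
            dpre = dg * g * (1 - g)
            grads = {"w": dw, "b": np.array([db])}
            params = {"w": self.w, "b": np.array([self.b])}
            off = 0
            for s, c in enumerate(sizes):
                grads[f"a{s}"] = dpre[off : off + c]
                grads[f"s{s}"] = dpre[off : off + c] * pooled_means[s]
                params[f"a{s}"] = self.state.gate_bias[s]
                params[f"s{s}"] = self.state.gate_slope[s]
                off += c
            self.opt.step(params, grads)
            self.b = float(params["b"][0])


def _train_target(
    train_patches,
    train_labels,
    val_patches,
    val_labels,
    cfg: NetworkConfig,
    seed: int,
    source: SourceModel | None,
    lam: float,
    epochs: int,
    batch_size: int,
    lr: float,
    freeze_gates: bool,
    adapt_gates: bool,
    train_ids=None,
    val_ids=None,
):
    if train_ids is not None and val_ids is not None:
        overlap = set(train_ids) & set(val_ids)
        if overlap:
            raise LeakageError(f"patients in both train and val: {sorted(overlap)[:5]}")
    if lam < 0:
        raise ParameterError("lambda must be >= 0")

    x_tr = patches_to_array(train_patches)
    y_tr = np.asarray(train_labels, dtype=np.int64)
    x_va = patches_to_array(val_patches)
    y_va = np.asarray(val_labels, dtype=np.int64)
    _check_classes(y_tr)

    rng = np.random.default_rng(seed)
    net = StageConvNet(cfg.scaled_channels, cfg.n_target_classes, rng)
    opt = Adam(lr=lr)
    shuffle_rng = np.random.default_rng(seed + 1)
    hist = TrainHistory(seed=seed, config=asdict(cfg))

    use_transfer = source is not None and lam > 0
    state = None
    probe = None
    src_tr_stages = src_val_pooled = None
    if source is not None:
        state = MetaSelectionState.init(cfg.scaled_channels, lam=lam)
        if use_transfer:
            # frozen source features on the target images, cached once
            _, src_tr_stages_list = source.net.forward(x_tr, keep_cache=False)
            src_tr_stages = src_tr_stages_list
            src_val_pooled = source.net.pooled_stage_features(x_va)
            if adapt_gates and not freeze_gates:
                probe = MetaProbe(state, sum(cfg.scaled_channels))

    for _ in range(epochs):
        order = shuffle_rng.permutation(len(x_tr))
        task_losses, con_losses = [], []
        for b0 in range(0, len(x_tr), batch_size):
            idx = order[b0 : b0 + batch_size]
            logits, t_stages = net.forward(x_tr[idx])
            loss, dlogits = softmax_cross_entropy(logits, y_tr[idx])
            task_losses.append(loss)
            if use_transfer:
                s_stages = [s[idx] for s in src_tr_stages]
                pooled_src = [s.mean(axis=(2, 3)) for s in s_stages]
                gates = state.gates(pooled_src)
                c_loss, stage_grads, m_grads = _constraint_grads(
                    t_stages, s_stages, state, gates
                )
                con_losses.append(c_loss)
                grads = net.backward(dlogits, stage_grads=stage_grads)
                # meta-net B: matching maps descend the same constraint
                mparams = {f"M{s}": state.matching[s] for s in range(len(m_grads))}
                mgrads = {f"M{s}": g for s, g in enumerate(m_grads)}
                opt.step(net.params, grads)
                opt.step(mparams, mgrads)
            else:
                con_losses.append(0.0)
                grads = net.backward(dlogits)
                opt.step(net.params, grads)
        if probe is not None:
            probe.update(src_val_pooled, y_va)
        hist.task_loss.append(float(np.mean(task_losses)))
        hist.constraint_loss.append(float(np.mean(con_losses)))
        val_scores = net.predict_proba(x_va)[:, 1]
        hist.val_auc.append(_auc(val_scores, y_va))
    hist.validate()
    return TargetModel(net=net, cfg=cfg, seed=seed, history=hist, meta=state)


def train_target_with_transfer(
    train_patches,
    train_labels,
    val_patches,
    val_labels,
    source: SourceModel,
    cfg: NetworkConfig,
    lam: float = 1.0,
    seed: int = 0,
    epochs: int = 8,
    batch_size: int = 32,
    lr: float = 1e-3,
    freeze_gates: bool = False,
    adapt_gates: bool = True,
    train_ids=None,
    val_ids=None,
) -> TargetModel:
    """Train the target network under the adaptive source-feature constraint.

    Alternating optimisation: target weights (and matching maps) descend
    cross-entropy plus the gated constraint on the training cohort; gate
    parameters descend the validation-probe loss once per epoch.
    """
    return _train_target(
        train_patches, train_labels, val_patches, val_labels, cfg, seed,
        source, lam, epochs, batch_size, lr, freeze_gates, adapt_gates,
        train_ids, val_ids,
    )


def train_nontransfer(
    train_patches,
    train_labels,
    val_patches,
    val_labels,
    cfg: NetworkConfig,
    seed: int = 0,
    epochs: int = 8,
    batch_size: int = 32,
    lr: float = 1e-3,
    train_ids=None,
    val_ids=None,
) -> TargetModel:
    """Train the target network from scratch, no source and no constraint."""
    return _train_target(
        train_patches, train_labels, val_patches, val_labels, cfg, seed,
        None, 0.0, epochs, batch_size, lr, True, False, train_ids, val_ids,
    )


# ---------------------------------------------------------------------------
# feature extraction & visualisation


def _feature_ids(cfg: NetworkConfig) -> list[str]:
    ids = []
    for s, c in enumerate(cfg.scaled_channels):
        ids.extend(f"s{s}_c{j}" for j in range(c))
    return ids


def extract_features(model: TargetModel | SourceModel, patches) -> FeatureMatrix:
    """Pooled per-stage activations, concatenated in stage order.

    Row ``i`` corresponds to ``patches[i]``; the column count equals
    ``sum(cfg.scaled_channels)`` (3904 under the default configuration).
    """
    patches = list(patches)
    x = patches_to_array(patches)
    chunk = max(1, int(2**24 / max(1, x.shape[2] * x.shape[3] * 64)))
    feats = []
    for b0 in range(0, len(x), chunk):
        feats.append(model.net.features(x[b0 : b0 + chunk]))
    values = np.concatenate(feats, axis=0)
    pids = [
        p.patient_id if isinstance(p, CtPatch) and p.patient_id else f"row{i}"
        for i, p in enumerate(patches)
    ]
    return FeatureMatrix(
        values=values, feature_ids=_feature_ids(model.cfg), patient_ids=pids
    )


@dataclass
class Heatmap:
    values: np.ndarray  # (H, W) in [0, 1]
    max_location: tuple
    stage: int
    channel: int
    constant: bool


def filter_response_heatmap(
    model: TargetModel | SourceModel, patch, feature_index: int
) -> Heatmap:
    """Upsampled activation map of one feature channel over a patch.

    ``feature_index`` addresses the concatenated feature vector; it is
    resolved to (stage, channel).  The map is min-max normalised to
    [0, 1]; a constant map is returned as zeros with ``constant=True``.
    """
    cfg = model.cfg
    if not (0 <= feature_index < cfg.feature_width):
        raise ParameterError(
            f"feature_index must be in [0, {cfg.feature_width}), got {feature_index}"
        )
    stage, channel, off = 0, feature_index, 0
    for s, c in enumerate(cfg.scaled_channels):
        if channel < c:
            stage = s
            break
        channel -= c
    x = patches_to_array([patch])
    _, stages = model.net.forward(x, keep_cache=False)
    amap = stages[stage][0, channel]
    size = x.shape[2]
    up = _sk_resize(amap, (size, size), order=1, mode="edge", preserve_range=True)
    rng_span = up.max() - up.min()
    if rng_span <= 1e-12:
        values = np.zeros_like(up)
        constant = True
    else:
        values = (up - up.min()) / rng_span
        constant = False
    max_rc = np.unravel_index(np.argmax(values), values.shape)
    return Heatmap(values=values, max_location=tuple(int(v) for v in max_rc),
                   stage=stage, channel=channel, constant=constant)
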