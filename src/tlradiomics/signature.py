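"""The transfer learning signature (TLS).

Two steps, strictly in order: (1) Mann-Whitney U screening keeps the
features that differ significantly between the two pathology groups;
(2) a sparse Bayesian extreme learning machine (SBELM) performs the
final selection and produces the per-patient signature score.

The SBELM used here is the linear-kernel variant: an identity "hidden
layer" plus bias feeding a Bernoulli-likelihood Bayesian linear model
with an automatic-relevance-determination (ARD) prior — i.e. ARD-sparse
Bayesian logistic regression.  Evidence maximisation with a Laplace
approximation prunes any weight whose precision alpha_j diverges, so the
retained set is an explicit feature selection.  A classical random
sigmoid hidden layer is available via ``SbelmConfig(hidden=...)``, in
which case pruning acts on hidden units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import DataError, NumericError, ParameterError, SchemaError
from .nn import sigmoid

__all__ = [
    "FeatureMatrix",
    "SbelmConfig",
    "SbelmModel",
    "mannwhitney_filter",
    "mannwhitney_u",
    "fit_sbelm",
    "tls_score",
]


@dataclass
class FeatureMatrix:
    """An (n_patients x n_features) real matrix with row/column ids."""

    values: np.ndarray
    feature_ids: list
    patient_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ParameterError("values must be 2-D")
        if self.values.shape != (len(self.patient_ids), len(self.feature_ids)):
            raise ParameterError("ids do not match matrix shape")
        if not np.isfinite(self.values).all():
            raise NumericError("feature matrix contains non-finite entries")

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df.insert(0, "patient_id", self.patient_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path)
        pids = df.pop("patient_id").tolist()
        return cls(values=df.to_numpy(float), feature_ids=list(df.columns),
                   patient_ids=pids)

    def select(self, feature_ids) -> np.ndarray:
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise SchemaError(f"features missing from matrix: {missing[:5]}")
        return self.values[:, [index[f] for f in feature_ids]]


# ---------------------------------------------------------------------------
# Mann-Whitney screening


def mannwhitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all label assignments when both groups have
    <= 8 observations (ties counted 1/2 in U, two-sided p as the
    probability of a U at least as far from its null mean); the
    tie-corrected normal approximation otherwise.  Returns (U, p).
    All-tied data give p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    u_obs = _u_stat(x, y)
    if np.all(pooled == pooled[0]):
        return u_obs, 1.0
    n1, n2 = len(x), len(y)
    if n1 <= 8 and n2 <= 8:
        mean_u = n1 * n2 / 2.0
        dev = abs(u_obs - mean_u)
        count = total = 0
        idx = range(n1 + n2)
        for comb in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u = _u_stat(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mean_u) >= dev - 1e-12:
                count += 1
        return u_obs, count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _u_stat(x, y) -> float:
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mannwhitney_filter(
    X: FeatureMatrix | np.ndarray, y, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature two-sided Mann-Whitney screen: (mask p < alpha, p-values).

    No multiplicity correction is applied; screening operates at the
    stated per-feature alpha.
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise DataError(f"need exactly two classes, got {classes}")
    g1 = values[y == classes[1]]
    g0 = values[y == classes[0]]
    pvals = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        _, pvals[j] = mannwhitney_u(g1[:, j], g0[:, j])
    return pvals < alpha, pvals


# ---------------------------------------------------------------------------
# SBELM


@dataclass(frozen=True)
class SbelmConfig:
    prune_threshold: float = 1e4
    tol: float = 1e-4
    max_iter: int = 200
    alpha_init: float = 1.0
    # Gamma(a, b) hyperprior on each ARD precision.  A flat hyperprior
    # (a = b = 0) under-penalises weakly informative features in the
    # Laplace-approximated logistic evidence; this weak proper prior
    # restores the expected pruning of null features.
    hyper_a: float = 1.0
    hyper_b: float = 1e-6
    hidden: str | None = None  # None = linear kernel; "sigmoid" = random ELM layer
    n_hidden: int = 100
    seed: int = 0


@dataclass
class SbelmModel:
    """Posterior summary of a fitted SBELM.

    ``weights`` are posterior means (Laplace mode) over retained
    features in standardised coordinates; the score is the logistic link
    applied to the linear predictor.
    """

    retained_features: list
    weights: np.ndarray
    intercept: float
    ard_precisions: dict
    feature_means: dict
    feature_sds: dict
    n_iter: int
    converged: bool
    null_model: bool
    config: SbelmConfig = field(default_factory=SbelmConfig)
    hidden_weights: np.ndarray | None = None
    hidden_bias: np.ndarray | None = None
    input_means: np.ndarray | None = None  # hidden variant only
    input_sds: np.ndarray | None = None
    input_feature_ids: list | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "retained_features": list(self.retained_features),
            "weights": [float(w) for w in self.weights],
            "intercept": float(self.intercept),
            "ard_precisions": {k: float(v) for k, v in self.ard_precisions.items()},
            "feature_means": {k: float(v) for k, v in self.feature_means.items()},
            "feature_sds": {k: float(v) for k, v in self.feature_sds.items()},
            "n_iter": self.n_iter,
            "converged": self.converged,
            "null_model": self.null_model,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SbelmModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            retained_features=payload["retained_features"],
            weights=np.asarray(payload["weights"], dtype=np.float64),
            intercept=payload["intercept"],
            ard_precisions=payload["ard_precisions"],
            feature_means=payload["feature_means"],
            feature_sds=payload["feature_sds"],
            n_iter=payload["n_iter"],
            converged=payload["converged"],
            null_model=payload["null_model"],
        )


def _laplace_map(phi, y, alphas, w0=None, max_newton=50, tol=1e-8):
    """MAP weights of Bayesian logistic regression with diagonal prior."""
    n, d = phi.shape
    w = np.zeros(d) if w0 is None else w0.copy()
    for _ in range(max_newton):
        p = sigmoid(phi @ w)
        grad = phi.T @ (p - y) + alphas * w
        r = np.maximum(p * (1 - p), 1e-10)
        h = phi.T @ (phi * r[:, None]) + np.diag(alphas)
        try:
            step = np.linalg.solve(h, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(h, grad, rcond=None)[0]
        w -= step
        if np.abs(step).max() < tol:
            break
    p = sigmoid(phi @ w)
    r = np.maximum(p * (1 - p), 1e-10)
    h = phi.T @ (phi * r[:, None]) + np.diag(alphas)
    return w, h


def fit_sbelm(
    X: FeatureMatrix | np.ndarray,
    y,
    cfg: SbelmConfig = SbelmConfig(),
    feature_ids=None,
) -> SbelmModel:
    """ARD evidence maximisation with Bernoulli likelihood.

    Candidate features are standardised (training mean/SD, frozen in the
    model), the MAP is found by Newton iteration under the current
    per-weight precisions, and hyperprior-regularised MacKay updates
    ``alpha_j <- (gamma_j + 2a) / (w_j^2 + 2b)`` prune any weight whose
    precision exceeds ``cfg.prune_threshold``.  The intercept carries a
    fixed, vague precision and is never pruned.  If every feature is
    pruned the model is flagged ``null_model`` and scores fall back to
    the intercept.
    """
    if isinstance(X, FeatureMatrix):
        feature_ids = list(X.feature_ids)
        values = X.values
    else:
        values = np.asarray(X, dtype=np.float64)
        if feature_ids is None:
            feature_ids = [f"f{j}" for j in range(values.shape[1])]
    y = np.asarray(y, dtype=np.float64)
    if values.shape[0] < 10:
        raise DataError("need at least 10 samples")
    if values.shape[1] < 1:
        raise DataError("need at least one screened feature")
    if len(np.unique(y)) != 2:
        raise DataError("need exactly two classes")

    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    z = (values - mu) / sd

    hidden_w = hidden_b = None
    input_mu = input_sd = input_ids = None
    if cfg.hidden == "sigmoid":
        rng = np.random.default_rng(cfg.seed)
        hidden_w = rng.standard_normal((z.shape[1], cfg.n_hidden))
        hidden_b = rng.standard_normal(cfg.n_hidden)
        input_mu, input_sd, input_ids = mu, sd, list(feature_ids)
        z = sigmoid(z @ hidden_w + hidden_b)
        feature_ids = [f"h{j}" for j in range(cfg.n_hidden)]
        mu_h, sd_h = z.mean(axis=0), z.std(axis=0)
        sd_h[sd_h == 0] = 1.0
        z = (z - mu_h) / sd_h
        mu, sd = mu_h, sd_h
    elif cfg.hidden is not None:
        raise ParameterError(f"unknown hidden layer {cfg.hidden!r}")

    # collapse exactly duplicated (standardised) columns: they carry no
    # extra information and break identifiability of the ARD solution
    _, first_idx = np.unique(z.round(12), axis=1, return_index=True)
    unique_cols = np.sort(first_idx)
    z = z[:, unique_cols]
    feature_ids = [feature_ids[j] for j in unique_cols]
    mu, sd = mu[unique_cols], sd[unique_cols]

    d = z.shape[1]
    active = np.arange(d)
    alphas = np.full(d, cfg.alpha_init)
    intercept_alpha = 1e-6
    w_full = None
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        phi = np.column_stack([np.ones(len(y)), z[:, active]])
        a = np.concatenate([[intercept_alpha], alphas[active]])
        w, h = _laplace_map(phi, y, a, w0=w_full)
        try:
            sigma = np.linalg.inv(h)
        except np.linalg.LinAlgError:
            sigma = np.linalg.pinv(h)
        gamma = 1.0 - a[1:] * np.diag(sigma)[1:]
        old_log_alpha = np.log(alphas[active])
        new_alpha = (np.maximum(gamma, 1e-12) + 2 * cfg.hyper_a) / (
            np.maximum(w[1:] ** 2, 1e-300) + 2 * cfg.hyper_b
        )
        alphas[active] = new_alpha
        keep = new_alpha < cfg.prune_threshold
        if keep.sum() == 0:
            active = active[:0]
            w_full = None
            break
        delta = np.abs(np.log(new_alpha[keep]) - old_log_alpha[keep]).max()
        if not np.all(keep):
            active = active[keep]
            w_full = None
        else:
            w_full = w
        if delta < cfg.tol:
            converged = True
            break
    if not converged and len(active) > 0:
        import warnings

        warnings.warn("SBELM did not converge within max_iter", RuntimeWarning)

    if len(active) == 0:
        # null model: intercept at the empirical log-odds
        p1 = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        return SbelmModel(
            retained_features=[], weights=np.zeros(0),
            intercept=float(np.log(p1 / (1 - p1))),
            ard_precisions={}, feature_means={}, feature_sds={},
            n_iter=it, converged=True, null_model=True, config=cfg,
            hidden_weights=hidden_w, hidden_bias=hidden_b,
            input_means=input_mu, input_sds=input_sd, input_feature_ids=input_ids,
        )

    phi = np.column_stack([np.ones(len(y)), z[:, active]])
    a = np.concatenate([[intercept_alpha], alphas[active]])
    w, _ = _laplace_map(phi, y, a)
    retained = [feature_ids[j] for j in active]
    return SbelmModel(
        retained_features=retained,
        weights=w[1:],
        intercept=float(w[0]),
        ard_precisions={feature_ids[j]: float(alphas[j]) for j in active},
        feature_means={f: float(m) for f, m in zip(retained, mu[active])},
        feature_sds={f: float(s) for f, s in zip(retained, sd[active])},
        n_iter=it,
        converged=converged,
        null_model=False,
        config=cfg,
        hidden_weights=hidden_w,
        hidden_bias=hidden_b,
        input_means=input_mu,
        input_sds=input_sd,
        input_feature_ids=input_ids,
    )


def tls_score(model: SbelmModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Signature scores in [0, 1]: logistic link on the posterior-mean weights."""
    if model.null_model:
        n = X.values.shape[0] if isinstance(X, FeatureMatrix) else np.asarray(X).shape[0]
        return np.full(n, float(sigmoid(model.intercept)))
    if model.hidden_weights is not None:
        # random-hidden-layer variant: rebuild retained hidden units from raw inputs
        if isinstance(X, FeatureMatrix):
            vals = X.select(model.input_feature_ids)
        else:
            vals = np.asarray(X, dtype=np.float64)
        z0 = (vals - model.input_means) / model.input_sds
        hid = sigmoid(z0 @ model.hidden_weights + model.hidden_bias)
        cols = [int(f[1:]) for f in model.retained_features]
        vals = hid[:, cols]
    elif isinstance(X, FeatureMatrix):
        vals = X.select(model.retained_features)
    else:
        vals = np.asarray(X, dtype=np.float64)
        if vals.shape[1] != len(model.retained_features):
            raise SchemaError(
                f"expected {len(model.retained_features)} columns, got {vals.shape[1]}"
            )
    mu = np.array([model.feature_means[f] for f in model.retained_features])
    sd = np.array([model.feature_sds[f] for f in model.retained_features])
    z = (vals - mu) / sd
    return sigmoid(z @ model.weights + model.intercept)
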