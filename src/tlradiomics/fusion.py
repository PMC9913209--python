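"""Clinical statistics and multimodal fusion.

Univariate statistics mirror standard cohort-table practice: continuous
variables get the Wilcoxon rank-sum test, categorical variables get
Pearson's chi-square without continuity correction unless any expected
cell count is below 5, in which case Fisher's exact test (full
margin-fixed enumeration, supporting 2 x k tables up to k = 5) is used.
Cohen's kappa quantifies interreader agreement on subjective findings.

The fusion model (TLRM — transfer learning radiomics model) is a sparse
Bayesian LASSO: Bayesian logistic regression with a hierarchical Laplace
(scale-mixture) prior optimised by EM (iteratively reweighted ridge,
whose fixed point is the L1-penalised mode), followed by hard
thresholding of standardised coefficients and an unpenalised refit on
the survivors.  The comparator clinical model is plain multivariable
maximum-likelihood logistic regression over gender, age, lobulated
shape and spiculated sign.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from math import inf, lgamma

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DataError,
    EnumerationLimitError,
    ParameterError,
    SchemaError,
)
from .nn import sigmoid
from .signature import mannwhitney_u

__all__ = [
    "cohen_kappa",
    "pearson_chi2_2xk",
    "fisher_exact_2xk",
    "wilcoxon_ranksum",
    "univariate_screen",
    "ScreeningReport",
    "TlrmModel",
    "fit_sparse_bayes_lasso",
    "tlrm_score",
    "ClinicalModel",
    "fit_clinical_logistic",
    "encode_clinical",
]

CLINICAL_BINARY = {
    "gender": {"women": 0, "men": 1},
    "margin": {"regular": 0, "irregular": 1},
    "lobulated": {"absence": 0, "presence": 1},
    "spiculated": {"absence": 0, "presence": 1},
}
CONTINUOUS_VARS = ("age", "nodule_size")


# ---------------------------------------------------------------------------
# agreement and univariate tests


def cohen_kappa(reader1, reader2) -> float:
    """Cohen's kappa = (p_o - p_e) / (1 - p_e); NaN when p_e = 1."""
    r1 = np.asarray(reader1)
    r2 = np.asarray(reader2)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise DataError("reader vectors must be 1-D and of equal length")
    cats = np.unique(np.concatenate([r1, r2]))
    n = len(r1)
    p_o = float(np.mean(r1 == r2))
    p_e = 0.0
    for c in cats:
        p_e += float(np.mean(r1 == c)) * float(np.mean(r2 == c))
    if abs(1.0 - p_e) < 1e-12:
        warnings.warn("kappa undefined: expected agreement is 1", RuntimeWarning)
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def pearson_chi2_2xk(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction: (chi2, df, p)."""
    t = np.asarray(table, dtype=np.float64)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ParameterError("table must be at least 2 x 2")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ParameterError("table entries must be non-negative finite counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DataError("table has a zero marginal")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def fisher_exact_2xk(table, max_tables: int = 2_000_000) -> float:
    """Two-sided Fisher exact p for a 2 x k table by full enumeration.

    All tables with the observed margins are enumerated; the p-value sums
    the (multivariate hypergeometric) probabilities of tables no more
    probable than the observed one.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ParameterError("table must be 2 x k")
    if (t < 0).any():
        raise ParameterError("counts must be non-negative")
    k = t.shape[1]
    if k > 5:
        raise EnumerationLimitError(f"2 x {k} exceeds the enumeration limit (k <= 5)")
    cols = t.sum(axis=0)
    r0 = int(t[0].sum())
    n = int(t.sum())
    if n == 0:
        raise DataError("empty table")

    space = 1
    for c in cols[:-1]:
        space *= int(c) + 1
    if space > max_tables:
        raise EnumerationLimitError(f"{space} candidate tables exceed limit")

    denom_log = _log_comb(n, r0)

    def log_prob(row0) -> float:
        return sum(_log_comb(int(c), int(x)) for c, x in zip(cols, row0)) - denom_log

    obs_lp = log_prob(t[0])
    total = 0.0
    p_val = 0.0
    ranges = [range(int(c) + 1) for c in cols[:-1]]
    for combo in product(*ranges):
        last = r0 - sum(combo)
        if last < 0 or last > cols[-1]:
            continue
        lp = log_prob(list(combo) + [last])
        pr = np.exp(lp)
        total += pr
        if lp <= obs_lp + 1e-9:
            p_val += pr
    return float(min(p_val / total, 1.0))


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -inf
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum test (same engine as the Mann-Whitney screen)."""
    return mannwhitney_u(x, y)


@dataclass
class ScreeningReport:
    """Per-variable univariate test results."""

    table: pd.DataFrame  # variable, test, statistic, p_value, significant, degenerate
    alpha: float = 0.05

    @property
    def significant(self) -> list:
        return self.table.loc[self.table["significant"], "variable"].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def univariate_screen(
    cohort: pd.DataFrame,
    label_col: str = "label",
    continuous=CONTINUOUS_VARS,
    alpha: float = 0.05,
    variables=None,
) -> ScreeningReport:
    """Screen cohort variables against the label.

    Continuous variables: Wilcoxon rank-sum.  Categorical variables:
    Pearson chi-square, or Fisher's exact test when any expected count
    is below 5.  Constant variables are reported with p = 1 and a
    degenerate flag.
    """
    if label_col not in cohort.columns:
        raise SchemaError(f"missing label column {label_col!r}")
    y = cohort[label_col].to_numpy()
    if len(np.unique(y)) != 2:
        raise DataError("label must have exactly two classes")
    if variables is None:
        variables = [
            c
            for c in cohort.columns
            if c not in (label_col, "patient_id", "cohort")
        ]
    rows = []
    for var in variables:
        col = cohort[var]
        degenerate = col.nunique() <= 1
        if degenerate:
            rows.append(
                dict(variable=var, test="degenerate", statistic=float("nan"),
                     p_value=1.0, significant=False, degenerate=True)
            )
            continue
        if var in continuous:
            x1 = col[y == np.max(y)].to_numpy(float)
            x0 = col[y == np.min(y)].to_numpy(float)
            stat, p = wilcoxon_ranksum(x1, x0)
            test = "wilcoxon"
        else:
            tab = pd.crosstab(cohort[var], y).to_numpy().T  # 2 x k
            expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
            if (expected < 5).any():
                try:
                    p = fisher_exact_2xk(tab)
                    stat = float("nan")
                    test = "fisher_exact"
                except EnumerationLimitError:
                    stat, _, p = pearson_chi2_2xk(tab)
                    test = "pearson_chi2"
            else:
                stat, _, p = pearson_chi2_2xk(tab)
                test = "pearson_chi2"
        rows.append(
            dict(variable=var, test=test, statistic=stat, p_value=p,
                 significant=p < alpha, degenerate=False)
        )
    return ScreeningReport(table=pd.DataFrame(rows), alpha=alpha)


# ---------------------------------------------------------------------------
# sparse Bayesian LASSO fusion (TLRM)


@dataclass
class TlrmModel:
    """The fused risk model over clinical factors, CT findings and TLS."""

    selected: list
    coefficients: np.ndarray  # on standardised covariates
    intercept: float
    prior_scale: float
    means: dict
    sds: dict
    candidates: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "selected": list(self.selected),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "prior_scale": float(self.prior_scale),
            "means": {k: float(v) for k, v in self.means.items()},
            "sds": {k: float(v) for k, v in self.sds.items()},
            "candidates": list(self.candidates),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TlrmModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            selected=payload["selected"],
            coefficients=np.asarray(payload["coefficients"], dtype=np.float64),
            intercept=payload["intercept"],
            prior_scale=payload["prior_scale"],
            means=payload["means"],
            sds=payload["sds"],
            candidates=payload.get("candidates", []),
        )


def _em_laplace_logistic(z, y, lam, max_iter=200, tol=1e-6):
    """MAP of logistic regression under a Laplace prior via EM.

    E-step: per-weight ridge precision lam / |w_j|; M-step: Newton solve.
    The fixed point is the L1-penalised mode, so small weights collapse
    to (numerical) zero.  Intercept unpenalised.
    """
    n, d = z.shape
    phi = np.column_stack([np.ones(n), z])
    # start from a mild ridge fit: w = 0 is an absorbing state of the EM
    w = _refit_logistic(z, y, ridge=1.0)
    for _ in range(max_iter):
        v = np.concatenate([[1e-8], lam / np.maximum(np.abs(w[1:]), 1e-8)])
        w_new = w.copy()
        for _ in range(50):
            p = sigmoid(phi @ w_new)
            grad = phi.T @ (p - y) + v * w_new
            r = np.maximum(p * (1 - p), 1e-10)
            h = phi.T @ (phi * r[:, None]) + np.diag(v)
            try:
                step = np.linalg.solve(h, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(h, grad, rcond=None)[0]
            w_new -= step
            if np.abs(step).max() < 1e-10:
                break
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
    return w


def fit_sparse_bayes_lasso(
    candidates: pd.DataFrame | np.ndarray,
    y,
    prior_scale: float | str = "auto",
    sparsity_eps: float = 1e-3,
    candidate_names=None,
) -> TlrmModel:
    """Select independent risk factors and fit the TLRM.

    ``candidates`` holds the univariately significant covariates plus the
    TLS score, one column each (numeric; binary variables coded 0/1).
    All columns are standardised before the penalised fit;
    ``prior_scale`` is the Laplace penalty weight lambda (larger = more
    shrinkage; ``"auto"`` uses sqrt(n * log p)).  Standardised
    coefficients below ``sparsity_eps`` in magnitude are dropped and the
    survivors refit without penalty (a vague ridge guards separation).
    """
    if isinstance(candidates, pd.DataFrame):
        candidate_names = list(candidates.columns)
        xmat = candidates.to_numpy(dtype=np.float64)
    else:
        xmat = np.asarray(candidates, dtype=np.float64)
        if candidate_names is None:
            candidate_names = [f"x{j}" for j in range(xmat.shape[1])]
    y = np.asarray(y, dtype=np.float64)
    n, d = xmat.shape
    if len(np.unique(y)) != 2:
        raise DataError("need exactly two classes")
    if n < 10 * d:
        warnings.warn(
            f"n = {n} is below the recommended 10 x {d} candidates", UserWarning
        )

    mu = xmat.mean(axis=0)
    sd = xmat.std(axis=0)
    sd[sd == 0] = 1.0
    z = (xmat - mu) / sd

    lam = float(np.sqrt(n * np.log(max(d, 2)))) if prior_scale == "auto" else float(
        prior_scale
    )
    if lam < 0:
        raise ParameterError("prior_scale must be >= 0")

    w = _em_laplace_logistic(z, y, lam)
    keep = np.abs(w[1:]) >= sparsity_eps
    selected = [candidate_names[j] for j in np.flatnonzero(keep)]

    if not keep.any():
        p1 = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        return TlrmModel(
            selected=[], coefficients=np.zeros(0),
            intercept=float(np.log(p1 / (1 - p1))), prior_scale=lam,
            means={}, sds={}, candidates=list(candidate_names),
        )

    zs = z[:, keep]
    # unpenalised refit (tiny ridge for numerical stability / separation)
    w_refit = _refit_logistic(zs, y)
    if not np.isfinite(w_refit).all() or np.abs(w_refit).max() > 1e3:
        warnings.warn("separation detected; keeping prior-regularised fit",
                      RuntimeWarning)
        w_refit = np.concatenate([[w[0]], w[1:][keep]])
    return TlrmModel(
        selected=selected,
        coefficients=w_refit[1:],
        intercept=float(w_refit[0]),
        prior_scale=lam,
        means={f: float(m) for f, m in zip(selected, mu[keep])},
        sds={f: float(s) for f, s in zip(selected, sd[keep])},
        candidates=list(candidate_names),
    )


def _refit_logistic(z, y, ridge=1e-6, max_newton=100):
    n, d = z.shape
    phi = np.column_stack([np.ones(n), z])
    w = np.zeros(d + 1)
    for _ in range(max_newton):
        p = sigmoid(phi @ w)
        grad = phi.T @ (p - y) + ridge * w
        r = np.maximum(p * (1 - p), 1e-10)
        h = phi.T @ (phi * r[:, None]) + ridge * np.eye(d + 1)
        try:
            step = np.linalg.solve(h, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(h, grad, rcond=None)[0]
        w -= step
        if np.abs(step).max() < 1e-10:
            break
    return w


def tlrm_score(model: TlrmModel, records: pd.DataFrame | dict) -> np.ndarray:
    """Risk prediction value in [0, 1] for records carrying the selected covariates."""
    if isinstance(records, dict):
        records = pd.DataFrame([records])
    missing = [c for c in model.selected if c not in records.columns]
    if missing:
        raise SchemaError(f"missing covariates: {missing}")
    if not model.selected:
        return np.full(len(records), float(sigmoid(model.intercept)))
    z = np.column_stack(
        [
            (records[c].to_numpy(float) - model.means[c]) / model.sds[c]
            for c in model.selected
        ]
    )
    return sigmoid(z @ model.coefficients + model.intercept)


# ---------------------------------------------------------------------------
# clinical comparator model


@dataclass
class ClinicalModel:
    covariates: list
    coefficients: np.ndarray
    intercept: float
    std_errors: np.ndarray
    penalised: bool = False

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.covariates if c not in records.columns]
        if missing:
            raise SchemaError(f"missing covariates: {missing}")
        x = records[self.covariates].to_numpy(float)
        return sigmoid(x @ self.coefficients + self.intercept)


def encode_clinical(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric coding of the cohort table: binaries 0/1, location one-hot."""
    out = cohort.copy()
    for col, mapping in CLINICAL_BINARY.items():
        if col in out.columns and out[col].dtype == object:
            bad = set(out[col].unique()) - set(mapping)
            if bad:
                raise SchemaError(f"unknown levels in {col}: {sorted(bad)}")
            out[col] = out[col].map(mapping)
    if "location" in out.columns and out["location"].dtype == object:
        dummies = pd.get_dummies(out["location"], prefix="loc").astype(int)
        out = pd.concat([out.drop(columns=["location"]), dummies], axis=1)
    return out


def fit_clinical_logistic(
    cohort: pd.DataFrame,
    covariates=("gender", "age", "lobulated", "spiculated"),
    label_col: str = "label",
) -> ClinicalModel:
    """Maximum-likelihood multivariable logistic regression comparator.

    Uses statsmodels Logit; on separation or non-convergence falls back
    to a weakly ridge-penalised fit with a warning.
    """
    import statsmodels.api as sm

    data = encode_clinical(cohort)
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise SchemaError(f"missing covariates: {missing}")
    x = data[list(covariates)].to_numpy(float)
    y = data[label_col].to_numpy(float)
    if len(np.unique(y)) != 2:
        raise DataError("label must have two classes")
    exog = sm.add_constant(x, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, exog).fit(disp=0)
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
        if not np.isfinite(params).all() or np.abs(params).max() > 1e3:
            raise np.linalg.LinAlgError("separation")
        return ClinicalModel(
            covariates=list(covariates),
            coefficients=params[1:],
            intercept=float(params[0]),
            std_errors=bse[1:],
            penalised=False,
        )
    except Exception:
        warnings.warn(
            "logistic MLE failed (possible separation); using ridge fallback",
            RuntimeWarning,
        )
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        w = _refit_logistic((x - mu) / sd, y, ridge=1.0)
        coef = w[1:] / sd
        intercept = float(w[0] - (mu * coef).sum())
        return ClinicalModel(
            covariates=list(covariates),
            coefficients=coef,
            intercept=intercept,
            std_errors=np.full(len(covariates), np.nan),
            penalised=True,
        )
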