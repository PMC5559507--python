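"""Inferential layer: transforms, composites, residualization, edge-wise
Spearman correlation with max-statistic permutation correction, and the
median-split ROC classification.

The analysis chain mirrors standard connectome-wide association practice:

1. the apathy score is square-root transformed (it is right-skewed; the
   transform is monotone, so rank statistics are unaffected — asserted as a
   property, not assumed);
2. connectivity values are log transformed and residualized edge-by-edge on
   the confounds (age, sex, education, MMS, LED) by ordinary least squares;
3. every edge's residuals are correlated with the outcome by Spearman rank;
4. family-wise error over the edge family is controlled by the max-statistic
   permutation scheme: the outcome is permuted across subjects, |rho| is
   recomputed for every edge, and each observed |rho| is referred to the
   permutation distribution of the family-wide maximum, with the
   add-one p convention p = (1 + #{max >= obs}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as ss
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

#: Confounds regressed out of every connectivity value before correlation.
DEFAULT_CONFOUNDS = ("age", "sex", "education", "MMS", "LED")

#: Cognitive z-score columns entering the initiation composite; True marks
#: variables where *smaller* raw values mean better performance (reversed).
INITIATION_TESTS: dict[str, bool] = {
    "phonemic_fluency": False,
    "semantic_fluency": False,
    "five_point": False,
    "tmt_a": True,
    "stroop_naming": True,
}

#: Internal-consistency acceptance threshold for the composite.
CRONBACH_THRESHOLD = 0.70

#: AES median split: low apathy <= 24, mild apathy >= 25.
AES_SPLIT = 24.5


def sqrt_transform_aes(aes: np.ndarray) -> np.ndarray:
    """Elementwise square root of the (non-negative) apathy scores."""
    aes = np.asarray(aes, dtype=float)
    if np.any(aes < 0):
        raise ValueError("apathy scores must be non-negative")
    return np.sqrt(aes)


def lilliefors_test(x: np.ndarray, method: str = "table") -> tuple[float, float]:
    """Kolmogorov-Smirnov test for normality with estimated mean and sd.

    ``method='table'`` uses the standard small-sample approximation;
    ``method='mc'`` draws a 10,000-replicate Monte-Carlo null.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("Lilliefors test needs n >= 5")
    if np.ptp(x) == 0:
        raise ValueError("Lilliefors test undefined for a constant sample")
    if method == "table":
        stat, p = _sm_lilliefors(x, dist="norm", pvalmethod="table")
    elif method == "mc":
        stat, p = _lilliefors_mc(x, n_draws=10_000)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stat), float(p)


def _lilliefors_statistic(x: np.ndarray) -> float:
    z = (np.sort(x) - x.mean()) / x.std(ddof=1)
    n = z.size
    cdf = ss.norm.cdf(z)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.max(ecdf_hi - cdf), np.max(cdf - ecdf_lo)))


def _lilliefors_mc(x: np.ndarray, n_draws: int, seed: int = 0) -> tuple[float, float]:
    stat = _lilliefors_statistic(x)
    rng = np.random.default_rng(seed)
    n = x.size
    null = np.array(
        [_lilliefors_statistic(rng.standard_normal(n)) for _ in range(n_draws)]
    )
    p = (1 + np.sum(null >= stat)) / (n_draws + 1)
    return stat, float(p)


@dataclass
class CompositeScore:
    """Initiation composite: mean of (sign-aligned) z-scores per subject."""

    initiation: np.ndarray
    cronbach_alpha: float
    consistent: bool  # alpha >= CRONBACH_THRESHOLD


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha = (k/(k-1)) (1 - sum(var_i)/var(total)) over columns."""
    items = np.asarray(items, dtype=float)
    k = items.shape[1]
    if k < 2:
        raise ValueError("Cronbach's alpha needs >= 2 items")
    item_var = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def build_initiation_score(
    cohort: pd.DataFrame,
    reverse_flags: "dict[str, bool] | None" = None,
) -> CompositeScore:
    """Average the z-scored initiation test variables into one composite.

    Each test column is z-scored across subjects; variables where smaller
    raw values indicate better performance are sign-flipped first, so larger
    composite values always mean better initiation.  Internal consistency is
    summarized by Cronbach's alpha (flagged below 0.70).
    """
    flags = dict(INITIATION_TESTS if reverse_flags is None else reverse_flags)
    if len(flags) < 2:
        raise ValueError("need at least 2 test variables")
    if len(cohort) < 3:
        raise ValueError("need at least 3 subjects")
    cols = []
    for name, reverse in flags.items():
        v = cohort[name].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"test variable {name!r} has zero variance")
        z = (v - v.mean()) / sd
        cols.append(-z if reverse else z)
    items = np.column_stack(cols)
    alpha = cronbach_alpha(items)
    return CompositeScore(
        initiation=items.mean(axis=1),
        cronbach_alpha=alpha,
        consistent=alpha >= CRONBACH_THRESHOLD,
    )


def residualize(
    values: np.ndarray,
    confounds: pd.DataFrame,
    log_transform: bool = True,
) -> np.ndarray:
    """Residuals of (log-)connectivity after OLS on the confounds.

    ``values`` is subjects x edges; each edge is regressed on the confound
    columns plus an intercept and replaced by its residual.  Collinear
    confounds raise with the offending column names.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n, _ = values.shape
    X = np.column_stack([np.ones(n)] + [confounds[c].to_numpy(float) for c in confounds.columns])
    if n <= X.shape[1]:
        raise ValueError(
            f"need more subjects ({n}) than regressors ({X.shape[1]}) for residualization"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, list(confounds.columns))
        raise ValueError(f"collinear confounds: {bad}")
    if log_transform:
        if np.any(values <= 0):
            raise ValueError("log transform requires strictly positive connectivity values")
        values = np.log(values)
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(1, X.shape[1]):
        others = np.delete(X, j, axis=1)
        proj, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ proj
        if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(X[:, j])):
            bad.append(names[j - 1])
    return bad or list(names)


def _rank_z(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mid-ranks standardized to zero mean / unit variance along axis."""
    r = ss.rankdata(x, axis=axis, method="average")
    r = r - r.mean(axis=axis, keepdims=True)
    norm = np.sqrt((r**2).sum(axis=axis, keepdims=True))
    out = np.zeros_like(r)
    np.divide(r, norm, out=out, where=norm > 0)
    return out


def edge_spearman(
    residuals: np.ndarray, outcome: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p for every edge against one outcome.

    ``residuals`` is subjects x edges.  Ties are mid-ranked; p uses the
    t-distribution approximation (the same scipy uses for n of this size).
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim == 1:
        residuals = residuals[:, None]
    outcome = np.asarray(outcome, dtype=float)
    n = outcome.size
    if n < 5:
        raise ValueError("Spearman correlation needs n >= 5")
    if np.ptp(outcome) == 0:
        raise ValueError("outcome is constant")
    zr = _rank_z(residuals, axis=0)
    zo = _rank_z(outcome[:, None], axis=0)[:, 0]
    rho = zr.T @ zo
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * ss.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def permutation_correct(
    residuals: np.ndarray,
    outcome: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Family-wise-corrected p per edge by the max-|rho| permutation scheme.

    For each of ``n_perm`` permutations the outcome is shuffled across
    subjects, every edge's Spearman |rho| recomputed, and the family maximum
    stored; the corrected p of an edge is
    (1 + #{permutation maxima >= observed |rho|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim == 1:
        residuals = residuals[:, None]
    outcome = np.asarray(outcome, dtype=float)
    n = outcome.size
    zr = _rank_z(residuals, axis=0)  # n x E
    zo = _rank_z(outcome[:, None], axis=0)[:, 0]
    obs = np.abs(zr.T @ zo)
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = zo[rng.permutation(n)]
    maxima = np.abs(zr.T @ perms).max(axis=0)  # n_perm family maxima
    exceed = (maxima[None, :] >= obs[:, None] - 1e-12).sum(axis=1)
    return (1.0 + exceed) / (n_perm + 1.0)


@dataclass
class EdgeCorrelationResult:
    """Per-edge Spearman statistics with permutation-corrected p-values."""

    table: pd.DataFrame  # columns: edge, rho, p_unc, p_corr
    n_subjects: int
    n_perm: int


def correlate_edges(
    residuals: np.ndarray,
    outcome: np.ndarray,
    edge_names: "list[str]",
    n_perm: int = 10_000,
    seed: int = 0,
) -> EdgeCorrelationResult:
    """Spearman + max-statistic permutation correction for an edge family."""
    rho, p_unc = edge_spearman(residuals, outcome)
    p_corr = permutation_correct(residuals, outcome, n_perm=n_perm, seed=seed)
    table = pd.DataFrame(
        {"edge": edge_names, "rho": rho, "p_unc": p_unc, "p_corr": p_corr}
    )
    return EdgeCorrelationResult(table=table, n_subjects=len(outcome), n_perm=n_perm)


@dataclass
class RocResult:
    """ROC of a single connectivity value against the apathy median split."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    sensitivity: float  # at the Youden-optimal threshold
    specificity: float
    youden_threshold: float


def median_split_roc(values: np.ndarray, aes: np.ndarray) -> RocResult:
    """ROC for classifying low (AES <= 24) vs mild (AES >= 25) apathy.

    ``values`` is used as the score as given (larger = more likely mild
    apathy; negate it for a marker that *decreases* with apathy).  AUC is
    computed by the trapezoidal rule over the full threshold sweep, and the
    reported operating point maximizes Youden's J = sensitivity +
    specificity - 1.
    """
    values = np.asarray(values, dtype=float)
    aes = np.asarray(aes, dtype=float)
    positive = aes > AES_SPLIT  # mild apathy
    if positive.all() or (~positive).all():
        raise ValueError("median split produced a single class")
    fpr, tpr, thr = _sk_roc_curve(positive.astype(int), values)
    roc_auc = float(_sk_auc(fpr, tpr))
    j = tpr - fpr
    best = int(np.argmax(j))
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=roc_auc,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        youden_threshold=float(thr[best]),
    )
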