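"""Spatial-stratified-heterogeneity (Geodetector) analysis.

The factor detector measures how much of the spatial variance of a
response Y (here: city-level overweight prevalence) is explained by an
ordinal stratification of an exposure X (here: a pollutant concentration):

    q = 1 - SSW / SST,   SSW = sum_h N_h * sigma_h^2,   SST = N * sigma^2,

with population-style (divide-by-N_h) variances, so q is exactly the
one-way ANOVA eta^2 and lies in [0, 1].  Significance comes from the
noncentral-F reference distribution of the q statistic, or from a
stratum-label permutation test.

The interaction detector recomputes q on the overlay (cross-classification)
of two stratifications and classifies the triple (q1, q2, q12) into five
interaction types:

    q12 < min(q1, q2)            -> nonlinear_weakening
    min <= q12 <= max            -> univariate_weakening
    q12 > max(q1, q2)            -> bivariate_enhancement
    q12 = q1 + q2  (within tol)  -> independent
    q12 > q1 + q2                -> nonlinear_enhancement

Because the overlay refines both partitions, q12 >= max(q1, q2) always
holds when q12 is computed here; the weakening branches are reachable only
for precomputed q triples.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StrataAssignment",
    "QResult",
    "InteractionResult",
    "discretize",
    "fisher_jenks_breaks",
    "factor_q",
    "q_significance",
    "interaction_q",
    "classify_interaction",
    "GeoDetector",
    "GeoDetectorResults",
    "INTERACTION_CATEGORIES",
]

logger = logging.getLogger(__name__)

INTERACTION_CATEGORIES = (
    "nonlinear_weakening",
    "univariate_weakening",
    "bivariate_enhancement",
    "independent",
    "nonlinear_enhancement",
)


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

@dataclass
class StrataAssignment:
    """Assignment of units to ordinal strata h = 1..L.

    `labels` are integer codes 1..L; every stratum is non-empty.
    `breakpoints` are the interior cut points (exposure units) that
    produced the assignment, empty for precomputed/overlay strata.
    """

    labels: np.ndarray
    L: int
    method: str
    breakpoints: np.ndarray = field(default_factory=lambda: np.array([]))
    requested_L: int | None = None
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        counts = np.bincount(self.labels, minlength=self.L + 1)[1:]
        if len(self.labels) and (np.any(counts == 0) or self.labels.min() < 1
                                 or self.labels.max() > self.L):
            raise ValueError("strata labels must cover 1..L with no empty stratum")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.L + 1)[1:]

    @classmethod
    def from_labels(cls, labels, method: str = "precomputed") -> "StrataAssignment":
        if isinstance(labels, str):
            labels = list(labels)
        codes, _ = pd.factorize(np.asarray(labels), sort=True)
        return cls(labels=codes + 1, L=int(codes.max()) + 1, method=method)


def fisher_jenks_breaks(values: np.ndarray, L: int) -> np.ndarray:
    """Optimal 1-D partition into L classes minimizing within-class SSQ
    (Fisher's exact dynamic program; returns L-1 interior break values)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def seg_cost(i: int, j: int) -> float:  # cost of x[i:j]
        s, s2, m = cs[j] - cs[i], cs2[j] - cs2[i], j - i
        return s2 - s * s / m

    # dp[k][j]: min cost of splitting x[:j] into k classes
    dp = np.full((L + 1, n + 1), np.inf)
    back = np.zeros((L + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for k in range(1, L + 1):
        for j in range(k, n + 1):
            best, arg = np.inf, k - 1
            for i in range(k - 1, j):
                c = dp[k - 1, i] + seg_cost(i, j)
                if c < best:
                    best, arg = c, i
            dp[k, j], back[k, j] = best, arg
    cuts = []
    j = n
    for k in range(L, 1, -1):
        j = back[k, j]
        cuts.append(j)
    cuts = sorted(cuts)
    # break value: midpoint between the segment boundary samples
    return np.array([(x[c - 1] + x[c]) / 2.0 for c in cuts])


def discretize(values, method: str = "quantile", L: int = 5) -> StrataAssignment:
    """Discretize a continuous exposure into L ordinal strata.

    method : 'quantile' (default), 'equal_interval', or 'natural_breaks'
        (Fisher-Jenks).  Duplicate quantile breaks are merged, so the
        effective number of strata L' <= L is recorded (with a warning).
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("exposure values must be finite")
    if L < 2:
        raise ValueError("L must be >= 2 for detector use")
    distinct = np.unique(x)
    if len(distinct) < 2:
        raise ValueError("need at least 2 distinct exposure values to stratify")

    warns: list[str] = []
    if L > len(distinct):
        warns.append(f"L={L} exceeds {len(distinct)} distinct values; strata will merge")

    if method == "quantile":
        breaks = np.quantile(x, np.arange(1, L) / L)
    elif method == "equal_interval":
        breaks = x.min() + np.arange(1, L) * (x.max() - x.min()) / L
    elif method == "natural_breaks":
        breaks = fisher_jenks_breaks(x, min(L, len(distinct)))
    else:
        raise ValueError(f"unknown discretization method: {method!r}")

    merged = np.unique(breaks)
    if len(merged) < len(breaks):
        warns.append(f"{len(breaks) - len(merged)} duplicate break(s) merged")

    # value == break goes to the lower stratum (bins are upper-inclusive)
    codes = np.searchsorted(merged, x, side="left") + 1
    # drop empty bins so labels are contiguous 1..L'
    codes, uniques = pd.factorize(codes, sort=True)
    codes = codes + 1
    eff_L = len(uniques)
    if eff_L < len(merged) + 1:
        warns.append(f"{len(merged) + 1 - eff_L} empty stratum(s) dropped")
    if eff_L < L:
        msg = f"effective strata L'={eff_L} < requested L={L}"
        warns.append(msg)
        _warnings.warn(msg, stacklevel=2)
        logger.warning(msg)

    return StrataAssignment(labels=codes, L=eff_L, method=method,
                            breakpoints=merged, requested_L=L, warnings=warns)


# ---------------------------------------------------------------------------
# Factor detector
# ---------------------------------------------------------------------------

@dataclass
class QResult:
    """Factor-detector output: q with its variance decomposition."""

    q: float
    SSW: float
    SST: float
    N: int
    L: int
    stratum_n: np.ndarray
    stratum_mean: np.ndarray
    stratum_var: np.ndarray
    F_stat: float
    p: float
    singleton_strata: int = 0
    p_is_infimum: bool = False

    def summary(self) -> str:
        lines = [
            "Factor detector (q-statistic)",
            "-----------------------------",
            f"N = {self.N}, L = {self.L} strata",
            f"q     : {self.q:.6f}",
            f"SSW   : {self.SSW:.6g}",
            f"SST   : {self.SST:.6g}",
            f"F     : {self.F_stat:.4f}" if np.isfinite(self.F_stat) else "F     : inf",
            f"p     : {self.p:.4g}" + ("  (infimum; q = 1)" if self.p_is_infimum else ""),
        ]
        if self.singleton_strata:
            lines.append(f"warning: {self.singleton_strata} singleton stratum(s) "
                         "contribute zero within-variance and inflate q")
        return "\n".join(lines)


def _stratum_moments(y: np.ndarray, labels: np.ndarray, L: int):
    n_h = np.bincount(labels, minlength=L + 1)[1:].astype(float)
    sum_h = np.bincount(labels, weights=y, minlength=L + 1)[1:]
    ssq_h = np.bincount(labels, weights=y ** 2, minlength=L + 1)[1:]
    mean_h = sum_h / n_h
    var_h = ssq_h / n_h - mean_h ** 2
    return n_h, mean_h, np.maximum(var_h, 0.0)


def factor_q(y, strata: StrataAssignment, significance: str = "ncf",
             n_perm: int = 999, seed: int | None = None) -> QResult:
    """q-statistic of a stratified exposure for the response y.

    SSW uses population (divide-by-N_h) stratum variances, so
    q = 1 - SSW/SST is identically the ANOVA eta^2.  Strata with a single
    member contribute zero to SSW and are flagged, since they inflate q.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(strata):
        raise ValueError("response and strata are not aligned")
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    sst = n * float(y.var())  # population variance
    if sst == 0:
        raise ValueError("constant response: q is undefined (SST = 0)")

    n_h, mean_h, var_h = _stratum_moments(y, strata.labels, strata.L)
    ssw = float((n_h * var_h).sum())
    q = 1.0 - ssw / sst
    q = min(max(q, 0.0), 1.0)
    singletons = int((n_h == 1).sum())
    if singletons:
        logger.warning("%d singleton stratum(s) in factor_q", singletons)

    L = strata.L
    if L < 2:
        # a single all-covering stratum explains nothing by construction
        f_stat = 0.0
        p, infimum = 1.0, False
    elif q >= 1.0 or ssw == 0.0:
        f_stat = np.inf
        p, infimum = 0.0, True
    else:
        f_stat = (n - L) / (L - 1) * q / (1.0 - q)
        infimum = False
        if significance == "ncf":
            p = _ncf_pvalue(f_stat, y, n_h, mean_h, n, L)
        elif significance == "permutation":
            p = _perm_pvalue(y, strata, q, n_perm, seed)
        else:
            raise ValueError(f"unknown significance method: {significance!r}")

    return QResult(q=q, SSW=ssw, SST=sst, N=n, L=L, stratum_n=n_h.astype(int),
                   stratum_mean=mean_h, stratum_var=var_h, F_stat=f_stat,
                   p=float(p), singleton_strata=singletons, p_is_infimum=infimum)


def _ncf_pvalue(f_stat: float, y: np.ndarray, n_h: np.ndarray,
                mean_h: np.ndarray, n: int, L: int) -> float:
    """Noncentral-F reference distribution of the q-statistic test."""
    sigma2 = float(y.var())
    lam = ((mean_h ** 2).sum() - (np.sqrt(n_h) * mean_h).sum() ** 2 / n) / sigma2
    lam = max(lam, 0.0)
    return float(stats.ncf.sf(f_stat, L - 1, n - L, lam))


def _perm_pvalue(y: np.ndarray, strata: StrataAssignment, q_obs: float,
                 n_perm: int, seed: int | None) -> float:
    """Stratum-label permutation null for q (vectorized over draws)."""
    rng = np.random.default_rng(seed)
    n = len(y)
    yp = rng.permuted(np.broadcast_to(y, (n_perm, n)), axis=1, out=np.empty((n_perm, n)))
    q_perm = _q_of_permutations(yp, strata)
    return float((1.0 + np.sum(q_perm >= q_obs - 1e-15)) / (n_perm + 1.0))


def _q_of_permutations(yp: np.ndarray, strata: StrataAssignment) -> np.ndarray:
    """q for each row of a (R, n) matrix of permuted responses.

    Uses SSW = sum(y^2) - sum_h (stratum sum)^2 / N_h, which is invariant
    in its first term under permutation, so only one matmul per batch of
    draws is needed.
    """
    n = yp.shape[1]
    onehot = np.zeros((n, strata.L))
    onehot[np.arange(n), strata.labels - 1] = 1.0
    n_h = strata.counts.astype(float)
    total_ssq = (yp ** 2).sum(axis=1)
    sums = yp @ onehot
    ssw = total_ssq - (sums ** 2 / n_h).sum(axis=1)
    row_mean = yp.mean(axis=1)
    sst = total_ssq - n * row_mean ** 2
    return 1.0 - ssw / sst


def q_significance(qr: QResult, n: int | None = None, L: int | None = None) -> float:
    """Noncentral-F p-value recomputed from a QResult's own moments.

    F = ((n-L)/(L-1)) * q/(1-q) referred to F(L-1, n-L; lambda) with
    lambda = (1/sigma^2) [sum_h Ybar_h^2 - (sum_h sqrt(N_h) Ybar_h)^2 / n].
    """
    n = qr.N if n is None else n
    L = qr.L if L is None else L
    if qr.q >= 1.0:
        return 0.0
    f_stat = (n - L) / (L - 1) * qr.q / (1.0 - qr.q)
    sigma2 = qr.SST / qr.N
    n_h = qr.stratum_n.astype(float)
    lam = ((qr.stratum_mean ** 2).sum()
           - (np.sqrt(n_h) * qr.stratum_mean).sum() ** 2 / n) / sigma2
    return float(stats.ncf.sf(f_stat, L - 1, n - L, max(lam, 0.0)))


# ---------------------------------------------------------------------------
# Interaction detector
# ---------------------------------------------------------------------------

@dataclass
class InteractionResult:
    """Interaction-detector output for one factor pair."""

    q1: float
    q2: float
    q12: float
    category: str
    tol: float
    overlay_L: int
    degenerate_overlay: bool = False

    def summary(self) -> str:
        return (f"q(X1) = {self.q1:.4f}, q(X2) = {self.q2:.4f}, "
                f"q(X1∩X2) = {self.q12:.4f} over {self.overlay_L} overlay zones "
                f"-> {self.category}")


def classify_interaction(q1: float, q2: float, q12: float,
                         tol: float = 1e-9) -> str:
    """Five-way interaction taxonomy from the (q1, q2, q12) triple.

    Exact equality q12 = q1 + q2 (independence) is tested within `tol`,
    since it never occurs exactly in floating point.
    """
    for v in (q1, q2, q12):
        if not (0.0 <= v <= 1.0):
            raise ValueError("q values must lie in [0, 1]")
    if abs(q12 - (q1 + q2)) <= tol:
        return "independent"
    if q12 > q1 + q2:
        return "nonlinear_enhancement"
    if q12 > max(q1, q2):
        return "bivariate_enhancement"
    if q12 >= min(q1, q2):
        return "univariate_weakening"
    return "nonlinear_weakening"


def overlay_strata(s1: StrataAssignment, s2: StrataAssignment) -> StrataAssignment:
    """Cross-classification of two stratifications: each non-empty cell
    (h1, h2) becomes one overlay zone."""
    if len(s1) != len(s2):
        raise ValueError("stratifications are not aligned")
    pair = s1.labels.astype(np.int64) * (s2.L + 1) + s2.labels
    codes, uniques = pd.factorize(pair, sort=True)
    return StrataAssignment(labels=codes + 1, L=len(uniques), method="overlay")


def interaction_q(y, s1: StrataAssignment, s2: StrataAssignment,
                  tol: float = 1e-9) -> InteractionResult:
    """q of the overlay of two stratifications, with its classification.

    The overlay refines both partitions, so q12 >= max(q1, q2) up to
    floating-point error.  An all-singleton overlay yields q12 = 1 and a
    degenerate-overlay warning.
    """
    y = np.asarray(y, dtype=float)
    ov = overlay_strata(s1, s2)
    q1 = factor_q(y, s1).q
    q2 = factor_q(y, s2).q
    r12 = factor_q(y, ov)
    degenerate = bool(np.all(r12.stratum_n == 1))
    if degenerate:
        _warnings.warn("overlay produced all-singleton zones; q12 = 1 is degenerate",
                       stacklevel=2)
    return InteractionResult(q1=q1, q2=q2, q12=r12.q,
                             category=classify_interaction(q1, q2, r12.q, tol),
                             tol=tol, overlay_L=ov.L, degenerate_overlay=degenerate)


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class GeoDetector:
    """Factor + interaction detector over a response and several exposures.

    Parameters
    ----------
    y : city-level response (e.g. overweight prevalence), length n.
    factors : mapping or DataFrame of continuous exposures (columns), or
        precomputed StrataAssignment objects.

    Examples
    --------
    >>> gd = GeoDetector.from_dataframe(df, response="prevalence",
    ...                                 factors=["pm25", "so2"])
    >>> res = gd.fit(method="quantile", n_strata=5)
    >>> print(res.summary())
    """

    def __init__(self, y, factors):
        self.y = np.asarray(y, dtype=float)
        if isinstance(factors, pd.DataFrame):
            factors = {c: factors[c].to_numpy() for c in factors.columns}
        self.factors = dict(factors)
        for name, v in self.factors.items():
            if not isinstance(v, StrataAssignment) and len(np.asarray(v)) != len(self.y):
                raise ValueError(f"factor {name!r} is not aligned with the response")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str,
                       factors: list[str]) -> "GeoDetector":
        return cls(df[response].to_numpy(), df[factors])

    def fit(self, method: str = "quantile", n_strata: int = 5,
            interactions: bool = True, significance: str = "ncf",
            n_perm: int = 999, seed: int | None = None,
            tol: float = 1e-9) -> "GeoDetectorResults":
        strata = {}
        for name, v in self.factors.items():
            strata[name] = (v if isinstance(v, StrataAssignment)
                            else discretize(v, method=method, L=n_strata))
        factor_results = {name: factor_q(self.y, s, significance=significance,
                                         n_perm=n_perm, seed=seed)
                          for name, s in strata.items()}
        inter = {}
        if interactions and len(strata) > 1:
            names = list(strata)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    inter[(a, b)] = interaction_q(self.y, strata[a], strata[b], tol=tol)
        return GeoDetectorResults(self, strata, factor_results, inter,
                                  method=method, n_strata=n_strata,
                                  significance=significance)


class GeoDetectorResults:
    """Fitted detector results: per-factor q table and pairwise interactions."""

    def __init__(self, model, strata, factor_results, interactions,
                 method, n_strata, significance):
        self.model = model
        self.strata = strata
        self.factor_results = factor_results
        self.interactions = interactions
        self.method = method
        self.n_strata = n_strata
        self.significance = significance

    def factor_table(self, levels=(0.05, 0.01), markers=("a", "b")) -> pd.DataFrame:
        rows = []
        for name, r in self.factor_results.items():
            mark = ""
            for lvl, m in sorted(zip(levels, markers), reverse=True):
                if r.p < lvl:
                    mark = m
            rows.append({"factor": name, "q": r.q, "p": r.p, "F": r.F_stat,
                         "L": r.L, "significance": mark})
        return pd.DataFrame(rows)

    def interaction_table(self) -> pd.DataFrame:
        rows = [{"x1": a, "x2": b, "q1": r.q1, "q2": r.q2, "q12": r.q12,
                 "category": r.category}
                for (a, b), r in self.interactions.items()]
        return pd.DataFrame(rows)

    def interaction_matrix(self) -> pd.DataFrame:
        """Symmetric matrix of q12 with factor q on the diagonal."""
        names = list(self.factor_results)
        m = pd.DataFrame(np.nan, index=names, columns=names)
        for name, r in self.factor_results.items():
            m.loc[name, name] = r.q
        for (a, b), r in self.interactions.items():
            m.loc[a, b] = m.loc[b, a] = r.q12
        return m

    def plot_interactions(self, ax=None):
        """Heatmap of the interaction-q matrix (requires matplotlib)."""
        import matplotlib.pyplot as plt

        m = self.interaction_matrix()
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(m.to_numpy(), vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(m)), m.columns, rotation=45)
        ax.set_yticks(range(len(m)), m.index)
        ax.figure.colorbar(im, ax=ax, label="q")
        ax.set_title("Interaction detector: q(X1∩X2)")
        return ax

    def summary(self) -> str:
        lines = ["Geodetector analysis", "====================",
                 f"n = {len(self.model.y)} units, "
                 f"{len(self.factor_results)} factor(s), "
                 f"discretization: {self.method} (L={self.n_strata}), "
                 f"significance: {self.significance}", "",
                 "Factor detector:"]
        ft = self.factor_table()
        lines.append(ft.to_string(index=False,
                                  float_format=lambda v: f"{v:.4f}"))
        if self.interactions:
            lines += ["", "Interaction detector:"]
            it = self.interaction_table()
            lines.append(it.to_string(index=False,
                                      float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)
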