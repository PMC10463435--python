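"""Global and local spatial autocorrelation of a city-level outcome.

`Moran` computes the global Moran's I

    I = sum_ij w_ij (x_i - xbar)(x_j - xbar) / (S^2 * sum_ij w_ij),
    S^2 = (1/n) sum_i (x_i - xbar)^2,

with E(I) = -1/(n-1) and a Z score under the normality or randomization
assumption (Cliff & Ord moments), or a conditional permutation null.

`GiStar` computes per-unit Getis-Ord statistics: the raw concentration
ratio G_i = sum_j w_ij x_j / sum_j x_j together with the standardized
Gi*/Gi z-scores (Ord & Getis 1995), and maps z to hot/cold-spot classes at
the 90/95/99% levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .weights import SpatialWeights

__all__ = [
    "Moran",
    "MoranResult",
    "GiStar",
    "GiStarResult",
    "morans_i",
    "gi_star",
    "classify_hotspots",
    "HOTSPOT_CLASSES",
]

HOTSPOT_CLASSES = ("cold_99", "cold_95", "cold_90", "not_significant",
                   "hot_90", "hot_95", "hot_99")


def _check_aligned(values: np.ndarray, w: SpatialWeights) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) != w.n:
        raise ValueError(f"values length {values.shape} does not match weights n={w.n}")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    return values


# ---------------------------------------------------------------------------
# Global Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    """Global Moran's I with its null moments and inference."""

    I: float
    expected: float
    variance: float
    z: float
    p: float
    n: int
    S2: float
    inference: str
    n_perm: int | None = None
    perm_values: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "Global Moran's I",
            "----------------",
            f"n units        : {self.n}",
            f"I              : {self.I:.6f}",
            f"E(I)           : {self.expected:.6f}",
            f"VAR(I)         : {self.variance:.6g}",
            f"Z              : {self.z:.4f}",
            f"p (two-sided)  : {self.p:.4g}",
            f"inference      : {self.inference}"
            + (f" ({self.n_perm} permutations)" if self.n_perm else ""),
        ]
        return "\n".join(lines)


def _moran_statistic(z: np.ndarray, m: np.ndarray, s2: float, w_sum: float) -> float:
    return float(z @ m @ z) / (s2 * w_sum)


def morans_i(
    values,
    w: SpatialWeights,
    inference: str = "randomization",
    n_perm: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I for `values` under the weights `w`.

    inference : 'normal', 'randomization' (Cliff-Ord analytic moments) or
        'permutation' (conditional randomization with `n_perm` draws).
    Raises on constant values (S^2 = 0 leaves I undefined).
    """
    x = _check_aligned(values, w)
    n = w.n
    m = w.matrix.copy()
    np.fill_diagonal(m, 0.0)  # i != j in the double sum
    w_sum = m.sum()
    if w_sum == 0:
        raise ValueError("weights sum to zero; no connectivity")

    z = x - x.mean()
    s2 = float(z @ z) / n
    if s2 == 0:
        raise ValueError("constant values: Moran's I is undefined (S^2 = 0)")

    I = _moran_statistic(z, m, s2, w_sum)
    e_i = -1.0 / (n - 1)

    # Cliff-Ord moment ingredients
    s1 = 0.5 * ((m + m.T) ** 2).sum()
    s2_sum = ((m.sum(axis=1) + m.sum(axis=0)) ** 2).sum()
    w2 = w_sum ** 2

    if inference == "normal":
        var = (n * n * s1 - n * s2_sum + 3 * w2) / (w2 * (n * n - 1)) - e_i ** 2
        perm_vals = None
        np_used = None
    elif inference == "randomization":
        b2 = n * float((z ** 4).sum()) / float(z @ z) ** 2
        num = (n * ((n * n - 3 * n + 3) * s1 - n * s2_sum + 3 * w2)
               - b2 * ((n * n - n) * s1 - 2 * n * s2_sum + 6 * w2))
        var = num / ((n - 1) * (n - 2) * (n - 3) * w2) - e_i ** 2
        perm_vals = None
        np_used = None
    elif inference == "permutation":
        rng = np.random.default_rng(seed)
        zp = rng.permuted(np.broadcast_to(z, (n_perm, n)), axis=1, out=np.empty((n_perm, n)))
        perm_vals = np.einsum("ri,ri->r", zp @ m, zp) / (s2 * w_sum)
        var = float(perm_vals.var(ddof=1))
        np_used = n_perm
    else:
        raise ValueError(f"unknown inference: {inference!r}")

    if inference == "permutation":
        mu = float(perm_vals.mean())
        zscore = (I - mu) / np.sqrt(var) if var > 0 else np.nan
        p = (1.0 + np.sum(np.abs(perm_vals - e_i) >= abs(I - e_i))) / (n_perm + 1.0)
    else:
        zscore = (I - e_i) / np.sqrt(var) if var > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(zscore))

    return MoranResult(I=I, expected=e_i, variance=var, z=zscore, p=float(p),
                       n=n, S2=s2, inference=inference, n_perm=np_used,
                       perm_values=perm_vals)


class Moran:
    """Model object for global Moran's I of one outcome on one weights set.

    Examples
    --------
    >>> res = Moran(prevalence, w).fit(inference="randomization")
    >>> print(res.summary())
    """

    def __init__(self, values, weights: SpatialWeights):
        self.values = _check_aligned(values, weights)
        self.weights = weights

    def fit(self, inference: str = "randomization", n_perm: int = 999,
            seed: int | None = None) -> MoranResult:
        return morans_i(self.values, self.weights, inference=inference,
                        n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Getis-Ord Gi* / Gi
# ---------------------------------------------------------------------------

@dataclass
class GiStarResult:
    """Per-unit Getis-Ord statistics, z-scores and hotspot classes."""

    ids: list
    raw: np.ndarray
    z: np.ndarray
    classes: list
    include_self: bool

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"unit": self.ids, "G": self.raw, "z": self.z,
                             "hotspot": self.classes})

    def summary(self) -> str:
        from collections import Counter

        counts = Counter(self.classes)
        name = "Gi*" if self.include_self else "Gi"
        lines = [f"Getis-Ord {name} hotspot analysis", "-" * 32,
                 f"n units : {len(self.ids)}"]
        for c in HOTSPOT_CLASSES:
            if counts.get(c):
                lines.append(f"{c:>16} : {counts[c]}")
        return "\n".join(lines)


def classify_hotspots(z) -> list:
    """Map z-scores to hot/cold-spot confidence classes.

    |z| >= 2.576 -> 99%, >= 1.96 -> 95%, >= 1.645 -> 90%; the sign decides
    hot (high-value cluster) vs cold.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    out = []
    for v in z:
        a = abs(v)
        if a >= 2.576:
            lvl = "99"
        elif a >= 1.96:
            lvl = "95"
        elif a >= 1.645:
            lvl = "90"
        else:
            out.append("not_significant")
            continue
        out.append(("hot_" if v > 0 else "cold_") + lvl)
    return out


def gi_star(values, w: SpatialWeights, include_self: bool = True) -> GiStarResult:
    """Getis-Ord Gi* (self-inclusive, default) or Gi per unit.

    The raw statistic is the value-mass ratio sum_j w_ij x_j / sum_j x_j;
    z-scores use the exact Ord-Getis first two moments under the
    randomization null, matching the `include_self` convention.
    """
    x = _check_aligned(values, w)
    n = w.n
    if x.sum() == 0:
        raise ValueError("values sum to zero: raw G is undefined")

    m = w.matrix.copy()
    if include_self and not w.includes_self:
        # treat the unit as one more neighbor: self-weight = the row's
        # largest neighbor weight (1 for binary, 1/k for row-standardized
        # knn), then restore row sums of 1 if the input was standardized
        np.fill_diagonal(m, np.where(m.max(axis=1) > 0, m.max(axis=1), 1.0))
        if w.row_standardized:
            m = m / m.sum(axis=1, keepdims=True)
    elif not include_self:
        np.fill_diagonal(m, 0.0)

    lag = m @ x
    raw = lag / x.sum()

    wi = m.sum(axis=1)
    s1i = (m ** 2).sum(axis=1)

    if include_self:
        xbar = x.mean()
        s = np.sqrt((x ** 2).mean() - xbar ** 2)
        denom = s * np.sqrt((n * s1i - wi ** 2) / (n - 1))
    else:
        xbar = (x.sum() - x) / (n - 1)
        s = np.sqrt(((x ** 2).sum() - x ** 2) / (n - 1) - xbar ** 2)
        denom = s * np.sqrt(((n - 1) * s1i - wi ** 2) / (n - 2))

    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(denom > 0, (lag - wi * xbar) / denom, 0.0)

    return GiStarResult(ids=list(w.ids), raw=raw, z=z,
                        classes=classify_hotspots(z), include_self=include_self)


class GiStar:
    """Model object for local Getis-Ord hot/cold-spot detection."""

    def __init__(self, values, weights: SpatialWeights, include_self: bool = True):
        self.values = _check_aligned(values, weights)
        self.weights = weights
        self.include_self = include_self

    def fit(self) -> GiStarResult:
        return gi_star(self.values, self.weights, include_self=self.include_self)
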