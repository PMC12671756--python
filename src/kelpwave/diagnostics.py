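"""Model-checking and group-comparison tests.

Breusch–Pagan heteroscedasticity test (studentized/Koenker by default) on an
auxiliary OLS fit, Moran's I spatial autocorrelation with inverse-distance
weights and the analytic randomization variance, the Wilcoxon rank-sum test
(exact enumeration for small untied samples, normal approximation with tie and
continuity corrections otherwise), and Levene's test for homogeneity of
variances (median-centred Brown–Forsythe by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "SpatialWeights",
    "inverse_distance_weights",
    "breusch_pagan",
    "morans_i",
    "wilcoxon_rank_sum",
    "levene_test",
]


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": float(self.statistic),
            "df": self.df,
            "p_value": float(self.p_value),
            **self.details,
        }


@dataclass(frozen=True)
class SpatialWeights:
    """Symmetric nonnegative spatial weight matrix with zero diagonal."""

    zone_ids: tuple[str, ...]
    w: np.ndarray
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        n = len(self.zone_ids)
        if w.shape != (n, n):
            raise ValueError("weight matrix shape must match zone count")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "zone_ids", tuple(self.zone_ids))


def inverse_distance_weights(
    zone_ids: Sequence[str], coords: Sequence[Sequence[float]]
) -> SpatialWeights:
    """Inverse Euclidean distance weights between zone centroids, zero diagonal.

    Coordinates must be in a consistent planar projection. Coincident centroids
    (zero distance off the diagonal) are rejected.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(zone_ids)
    if coords.shape != (n, 2):
        raise ValueError("coords must be an (n, 2) array matching zone_ids")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    off = ~np.eye(n, dtype=bool)
    if np.any(dist[off] == 0):
        raise ValueError("coincident zone centroids give undefined inverse distance")
    w = np.zeros((n, n))
    w[off] = 1.0 / dist[off]
    return SpatialWeights(zone_ids=tuple(str(z) for z in zone_ids), w=w, coords=coords)


def breusch_pagan(
    response: Sequence[float],
    covariates: Sequence[float] | np.ndarray,
    studentized: bool = True,
) -> TestResult:
    """Breusch–Pagan test for heteroscedasticity of an OLS fit.

    Fits OLS of the response on the covariates (intercept added), regresses the
    squared residuals on the same covariates, and forms the studentized
    (Koenker) statistic n·R²_aux ~ χ²_k. ``studentized=False`` gives the
    classical statistic ESS_aux / (2σ̂⁴) with σ̂² = RSS/n.
    """
    y = np.asarray(response, dtype=float)
    Xraw = np.asarray(covariates, dtype=float)
    if Xraw.ndim == 1:
        Xraw = Xraw[:, None]
    n, k = Xraw.shape
    if n <= k + 1:
        raise ValueError("need n > k + 1 observations")
    X = np.column_stack([np.ones(n), Xraw])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    u = resid**2

    coef_aux, *_ = np.linalg.lstsq(X, u, rcond=None)
    fitted_aux = X @ coef_aux
    ess_aux = float(np.sum((fitted_aux - u.mean()) ** 2))
    tss_aux = float(np.sum((u - u.mean()) ** 2))
    r2_aux = 0.0 if tss_aux == 0.0 else ess_aux / tss_aux

    if studentized:
        statistic = n * r2_aux
    else:
        sigma2 = float(np.mean(resid**2))
        statistic = ess_aux / (2.0 * sigma2**2)
    p = float(stats.chi2.sf(statistic, k))
    return TestResult(
        name="breusch_pagan",
        statistic=float(statistic),
        df=float(k),
        p_value=p,
        details={"studentized": studentized, "r2_aux": r2_aux, "n": n},
    )


def morans_i(values: Sequence[float], weights: SpatialWeights) -> TestResult:
    """Moran's I with the analytic randomization variance.

    I = (n/S0)·ΣΣ wᵢⱼ zᵢ zⱼ / Σ zᵢ² on centred values z; the null expectation
    is −1/(n−1). The two-sided p-value uses the normal approximation with the
    Cliff–Ord randomization variance, which needs n ≥ 4; for n = 3 the
    statistic is returned with p = NaN.
    """
    z = np.asarray(values, dtype=float)
    n = len(z)
    if n < 3:
        raise ValueError("Moran's I needs at least 3 zones")
    if n != len(weights.zone_ids):
        raise ValueError("values length must match weight matrix")
    if np.ptp(z) == 0:
        raise ValueError("Moran's I undefined for constant values")
    w = weights.w
    z = z - z.mean()
    s0 = float(w.sum())
    if s0 == 0:
        raise ValueError("all-zero weight matrix")
    num = float(z @ w @ z)
    I = (n / s0) * num / float(z @ z)
    expected = -1.0 / (n - 1)

    if n < 4:
        return TestResult(
            name="morans_i",
            statistic=float(I),
            p_value=float("nan"),
            details={"expected": expected, "n": n},
        )
    s1 = 0.5 * float(np.sum((w + w.T) ** 2))
    s2 = float(np.sum((w.sum(axis=0) + w.sum(axis=1)) ** 2))
    m2 = float(np.mean(z**2))
    m4 = float(np.mean(z**4))
    b2 = m4 / m2**2
    var = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - expected**2
    sd = float(np.sqrt(var))
    zscore = (I - expected) / sd
    p = float(2.0 * stats.norm.sf(abs(zscore)))
    return TestResult(
        name="morans_i",
        statistic=float(I),
        p_value=p,
        details={"expected": expected, "sd": sd, "z": zscore, "n": n},
    )


def wilcoxon_rank_sum(
    group_a: Sequence[float], group_b: Sequence[float]
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    The statistic W is the number of (a, b) pairs with a > b, ties counting ½
    (the U statistic of group a, matching the W printed by common statistical
    packages). The p-value is exact when min(n) ≤ 10 and there are no ties,
    else a normal approximation with tie and continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (min(len(a), len(b)) <= 10) and not has_ties
    res = stats.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        name="wilcoxon_rank_sum",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        details={"exact": exact, "ties": has_ties, "n_a": len(a), "n_b": len(b)},
    )


def levene_test(
    groups: Sequence[Sequence[float]],
    center: Literal["median", "mean"] = "median",
) -> TestResult:
    """Levene's test for homogeneity of variances across groups.

    One-way ANOVA F on absolute deviations from the group centre; the default
    median centring is the Brown–Forsythe variant. Degrees of freedom are
    (k−1, N−k).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least 2 observations")
    statistic, p = stats.levene(*arrays, center=center)
    k = len(arrays)
    n_total = sum(len(g) for g in arrays)
    return TestResult(
        name="levene",
        statistic=float(statistic),
        df=(float(k - 1), float(n_total - k)),
        p_value=float(p),
        details={"center": center},
    )
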