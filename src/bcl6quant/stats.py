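"""Group-level statistics on intensity distributions and HSCOREs.

Per-section normalized histograms are averaged point by point into a
group mean +/- SEM curve; group curves are summarised by percentiles and
by a fitted Gaussian, smoothed (for presentation and percentile
extraction only) with Stineman interpolation, and compared between
groups with the Mann-Whitney nonparametric test — both on scalar
summaries (HSCOREs) and point by point across grey levels.  A linear
regression of HSCORE against the fitted distribution mean quantifies
the agreement between the manual and the computer-assisted readings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

from ._stineman import stineman_interp
from .errors import ContractError, DegenerateInputError, FitWarning
from .quantification import IntensityDistribution, N_LEVELS

DEFAULT_ALPHA = 0.05
#: largest sample size for which the exact Mann-Whitney null distribution
#: is used (when the pooled sample is tie-free)
_EXACT_LIMIT = 25


@dataclass
class GroupDistribution:
    """Pointwise mean +/- SEM frequency curve for one patient group."""

    levels: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_sections: int
    group_label: str = ""

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.float64)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sem = np.asarray(self.sem, dtype=np.float64)
        if not (self.levels.shape == self.mean.shape == self.sem.shape):
            raise ContractError("levels, mean and sem must have equal length")
        if (self.sem < 0).any():
            raise ContractError("sem must be non-negative")
        if self.n_sections < 1:
            raise ContractError("a group needs at least one section")


@dataclass(frozen=True)
class PercentileSummary:
    """The five percentile intensities used to characterise a group curve."""

    p10: float
    p25: float
    p50: float
    p75: float
    p90: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("p10", "p25", "p50", "p75", "p90")}


@dataclass
class GaussianFit:
    """Least-squares Gaussian ``A * exp(-(x - mu)^2 / (2 sigma^2))``."""

    amplitude: float
    mu: float
    sigma: float
    residual_ss: float
    converged: bool = True


@dataclass
class PointwiseTest:
    """Per-grey-level Mann-Whitney comparison of two groups.

    ``tested`` is False at levels where every section of both groups
    has the same frequency (typically zero mass outside the intensity
    support); there ``p_values`` is 1 by convention.
    """

    levels: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    tested: np.ndarray
    alpha: float = DEFAULT_ALPHA


@dataclass
class RegressionResult:
    """Ordinary least-squares line with Pearson r and slope p-value."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def _as_matrix(dists: Sequence[IntensityDistribution] | np.ndarray) -> np.ndarray:
    if isinstance(dists, np.ndarray):
        mat = np.asarray(dists, dtype=np.float64)
        if mat.ndim != 2:
            raise ContractError("expected a (sections x levels) matrix")
        return mat
    flags = {d.normalized for d in dists}
    if len(flags) > 1:
        raise ContractError("cannot mix normalized and raw distributions")
    if flags == {False}:
        raise ContractError("group statistics require normalized distributions")
    return np.stack([d.counts for d in dists])


def mean_distribution(
    dists: Sequence[IntensityDistribution] | np.ndarray, group_label: str = ""
) -> GroupDistribution:
    """Point-by-point mean and SEM of per-section normalized histograms.

    SEM uses the n-1 sample standard deviation over sections; with a
    single section the SEM is zero everywhere.
    """
    mat = _as_matrix(dists)
    if mat.shape[0] < 1:
        raise ContractError("at least one distribution required")
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return GroupDistribution(
        levels=np.arange(mat.shape[1], dtype=np.float64),
        mean=mean,
        sem=sem,
        n_sections=n,
        group_label=group_label,
    )


def smooth_curve(curve: GroupDistribution, grid_factor: float = 4.0) -> GroupDistribution:
    """Smooth a group curve by Stineman interpolation on a denser grid.

    ``grid_factor`` multiplies the number of intervals of the level
    grid.  The interpolant passes through every original point and, by
    the scheme's overshoot suppression, introduces no new local extrema
    beyond those of the data.  Interpolated frequencies are clipped at
    zero; the SEM band is interpolated alongside the mean.
    """
    if grid_factor <= 0:
        raise ContractError("grid_factor must be positive")
    if curve.levels.size < 3:
        raise ContractError("smoothing requires at least 3 points")
    n_new = int(round((curve.levels.size - 1) * grid_factor)) + 1
    grid = np.linspace(curve.levels[0], curve.levels[-1], n_new)
    mean = np.maximum(stineman_interp(grid, curve.levels, curve.mean), 0.0)
    sem = np.maximum(stineman_interp(grid, curve.levels, curve.sem), 0.0)
    return GroupDistribution(
        levels=grid,
        mean=mean,
        sem=sem,
        n_sections=curve.n_sections,
        group_label=curve.group_label,
    )


def distribution_percentiles(
    curve: GroupDistribution,
    probs: Sequence[float] = (10, 25, 50, 75, 90),
) -> PercentileSummary:
    """Percentile intensities of a mean curve treated as a density.

    The cumulative mass is accumulated over levels carrying positive
    mass; each requested probability is inverted on that CDF with
    linear interpolation between consecutive mass-carrying levels (a
    point mass therefore returns its own level for every percentile).
    """
    mass = np.asarray(curve.mean, dtype=np.float64)
    if (mass < 0).any():
        raise ContractError("mean curve must be non-negative")
    total = mass.sum()
    if total <= 0:
        raise DegenerateInputError("zero total mass: percentiles undefined")
    support = np.flatnonzero(mass > 0)
    x = curve.levels[support]
    cum = np.cumsum(mass[support]) / total
    out = []
    for prob in probs:
        q = prob / 100.0
        if not 0.0 <= q <= 1.0:
            raise ContractError("probabilities must lie in [0, 100]")
        i = int(np.searchsorted(cum, q))
        i = min(i, x.size - 1)
        if i == 0:
            out.append(float(x[0]))
        else:
            c0, c1 = cum[i - 1], cum[i]
            out.append(float(x[i - 1] + (q - c0) / (c1 - c0) * (x[i] - x[i - 1])))
    if len(out) == 5:
        return PercentileSummary(*out)
    return out  # type: ignore[return-value]


def mann_whitney(
    a: Iterable[float], b: Iterable[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test between two scalar samples.

    Returns the U statistic of sample ``a`` (midrank tie handling) and
    the p-value: exact for small tie-free samples, otherwise the
    tie-corrected normal approximation (no continuity correction, so
    identical samples give p = 1 exactly).
    """
    a = np.asarray(list(a) if not isinstance(a, np.ndarray) else a, dtype=np.float64)
    b = np.asarray(list(b) if not isinstance(b, np.ndarray) else b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ContractError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        # no information about location: U at its null mean, p = 1
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and max(a.size, b.size) <= _EXACT_LIMIT:
        res = sps.mannwhitneyu(a, b, alternative=alternative, method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative=alternative, method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pointwise_mann_whitney(
    group_a: Sequence[IntensityDistribution] | np.ndarray,
    group_b: Sequence[IntensityDistribution] | np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    correction: str | None = None,
) -> PointwiseTest:
    """Mann-Whitney test applied point by point across grey levels.

    At each level the per-section normalized frequencies of the two
    groups are compared; levels with p <= ``alpha`` are flagged.  By
    default the raw point-by-point p-values are reported without
    multiple-testing correction; ``correction='bh'`` applies the
    Benjamini-Hochberg procedure over the tested levels.
    """
    mat_a = _as_matrix(group_a)
    mat_b = _as_matrix(group_b)
    if mat_a.shape[0] < 2 or mat_b.shape[0] < 2:
        raise ContractError("each group needs at least 2 sections")
    if mat_a.shape[1] != mat_b.shape[1]:
        raise ContractError("groups must share the same level grid")
    if not 0 < alpha < 1:
        raise ContractError("alpha must be in (0, 1)")
    n_levels = mat_a.shape[1]
    p = np.ones(n_levels)
    tested = np.zeros(n_levels, dtype=bool)
    for lvl in range(n_levels):
        col = np.concatenate([mat_a[:, lvl], mat_b[:, lvl]])
        if np.unique(col).size == 1:
            continue
        tested[lvl] = True
        _, p[lvl] = mann_whitney(mat_a[:, lvl], mat_b[:, lvl])
    if correction == "bh":
        p = p.copy()
        p[tested] = sps.false_discovery_control(p[tested], method="bh")
    elif correction is not None:
        raise ContractError(f"unknown correction {correction!r}")
    return PointwiseTest(
        levels=np.arange(n_levels, dtype=np.float64),
        p_values=p,
        significant=tested & (p <= alpha),
        tested=tested,
        alpha=alpha,
    )


def _gaussian(x: np.ndarray, amplitude: float, mu: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _curve_xy(curve: GroupDistribution | IntensityDistribution) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, IntensityDistribution):
        return np.arange(N_LEVELS, dtype=np.float64), curve.counts.astype(np.float64)
    return curve.levels, curve.mean


def fit_gaussian(
    curve: GroupDistribution | IntensityDistribution, max_evals: int = 10_000
) -> GaussianFit:
    """Least-squares Gaussian fit of an intensity curve.

    Initialised from the curve's moments (amplitude = maximum, mu =
    mass-weighted mean, sigma = mass-weighted standard deviation).  If
    the optimiser fails to converge within ``max_evals`` evaluations a
    :class:`FitWarning` is issued and the moment-based initial estimate
    is returned with ``converged=False``.
    """
    x, y = _curve_xy(curve)
    if np.count_nonzero(y > 0) < 4:
        raise ContractError("Gaussian fit requires >= 4 points with positive mass")
    total = y.sum()
    mu0 = float((x * y).sum() / total)
    sigma0 = float(np.sqrt(((x - mu0) ** 2 * y).sum() / total)) or 1.0
    a0 = float(y.max())
    p0 = (a0, mu0, sigma0)
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, x, y, p0=p0, maxfev=max_evals,
            ftol=1e-14, xtol=1e-14, gtol=1e-14,
        )
    except RuntimeError:
        warnings.warn(
            "Gaussian fit did not converge; returning moment estimates", FitWarning
        )
        rss = float(((y - _gaussian(x, *p0)) ** 2).sum())
        return GaussianFit(a0, mu0, sigma0, rss, converged=False)
    amplitude, mu, sigma = float(popt[0]), float(popt[1]), float(abs(popt[2]))
    rss = float(((y - _gaussian(x, amplitude, mu, sigma)) ** 2).sum())
    return GaussianFit(amplitude, mu, sigma, rss, converged=True)


def correlate_hscore(
    pairs: Sequence[tuple[float, float]]
) -> RegressionResult:
    """OLS regression of HSCORE against per-section distribution mean.

    Quantifies the agreement between the manual semi-quantitative score
    and the computer-assisted intensity measurement; returns slope,
    intercept, Pearson r and the two-sided p-value for slope != 0.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ContractError("pairs must be (hscore, distribution_mean) tuples")
    if arr.shape[0] < 3:
        raise ContractError("regression requires at least 3 pairs")
    if not np.isfinite(arr).all():
        raise ContractError("regression inputs must be finite")
    hs, means = arr[:, 0], arr[:, 1]
    if np.ptp(hs) == 0 or np.ptp(means) == 0:
        raise DegenerateInputError("zero variance in regression input")
    res = sps.linregress(means, hs)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=arr.shape[0],
    )
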