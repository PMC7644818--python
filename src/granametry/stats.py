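"""Statistical reporting: mean ± SEM, histogram Gaussian fits, rank tests.

Mirrors how thylakoid morphometry is conventionally reported: per-group
mean ± SEM tables over individual layer repeats, Gaussian fits (with R²)
to width histograms, two-sided Mann–Whitney rank-sum tests for dark-vs-
light comparisons, and the Pearson correlation between the two
repeat-distance estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps

from .errors import BinningError, FitQualityError, ValidationError

#: Largest n1*n2 for which the exact Mann-Whitney null distribution is used.
EXACT_MWU_LIMIT = 10_000


def _check_finite(values, name="values") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class GroupSummary:
    """n, mean, and SEM (sd with n-1 denominator over sqrt(n)), in nm."""

    n: int
    mean: float
    sem: float

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        arr = _check_finite(values)
        n = arr.size
        sem = 0.0 if n < 2 else float(arr.std(ddof=1) / math.sqrt(n))
        return cls(n=n, mean=float(arr.mean()), sem=sem)

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.sem:.2f} nm (n={self.n})"


def summarize(values) -> GroupSummary:
    """Mean ± SEM of a group of width measurements."""
    return GroupSummary.from_values(values)


@dataclass(frozen=True)
class GaussianFitResult:
    """Least-squares Gaussian through histogram bin counts."""

    mu: float
    sigma: float
    amplitude: float
    r_squared: float
    bin_width: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValidationError("r_squared must lie in [0, 1]")


def fit_gaussian_hist(values, bin_width: float = 0.5) -> GaussianFitResult:
    """Fit amplitude*exp(-(x-mu)^2 / (2 sigma^2)) to histogram counts.

    Bins of the given width cover the data range; at least 5 non-empty
    bins are required.  R² is computed on bin counts against the fitted
    curve.
    """
    arr = _check_finite(values)
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    lo, hi = float(arr.min()), float(arr.max())
    nbins = max(int(math.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(arr, bins=edges)
    centers = edges[:-1] + bin_width / 2.0
    if np.count_nonzero(counts) < 5:
        raise BinningError(
            f"only {np.count_nonzero(counts)} non-empty bins; need >= 5"
        )

    def model(x, amp, mu, sig):
        return amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    p0 = [float(counts.max()), float(arr.mean()), max(float(arr.std(ddof=0)), bin_width)]
    try:
        popt, _ = optimize.curve_fit(
            model, centers, counts.astype(float), p0=p0,
            bounds=([0, lo - bin_width, bin_width / 100.0], [np.inf, hi + bin_width, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitQualityError(f"Gaussian histogram fit failed: {exc}") from exc
    yhat = model(centers, *popt)
    ss_res = float(np.sum((counts - yhat) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return GaussianFitResult(
        mu=float(popt[1]), sigma=float(popt[2]), amplitude=float(popt[0]),
        r_squared=r2, bin_width=bin_width,
    )


@dataclass(frozen=True)
class MWUResult:
    """Two-sided Mann-Whitney rank-sum test result."""

    u_statistic: float
    p_two_sided: float
    n1: int
    n2: int
    method: str  # "exact" | "normal_approx"

    def __post_init__(self) -> None:
        if not (0 <= self.u_statistic <= self.n1 * self.n2):
            raise ValidationError("U must lie in [0, n1*n2]")


def mann_whitney(a, b) -> MWUResult:
    """Two-sided Mann-Whitney U test of two independent groups.

    Uses the exact null distribution when the sample is small
    (n1*n2 <= 10,000) and tie-free, otherwise the tie-corrected normal
    approximation with continuity correction; the method used is recorded
    in the result.
    """
    xa = _check_finite(a, "a")
    xb = _check_finite(b, "b")
    has_ties = np.unique(np.concatenate([xa, xb])).size < xa.size + xb.size
    exact = (xa.size * xb.size <= EXACT_MWU_LIMIT) and not has_ties
    res = sps.mannwhitneyu(
        xa, xb, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return MWUResult(
        u_statistic=float(res.statistic),
        p_two_sided=min(float(res.pvalue), 1.0),
        n1=xa.size,
        n2=xb.size,
        method="exact" if exact else "normal_approx",
    )


def correlate_methods(pairs) -> float:
    """Pearson correlation of paired (Method 1, Method 2) repeat distances."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError("need >= 3 (m1, m2) pairs")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("pairs contain non-finite entries")
    if arr[:, 0].std() == 0 or arr[:, 1].std() == 0:
        raise ValidationError("zero variance in one margin")
    return float(sps.pearsonr(arr[:, 0], arr[:, 1]).statistic)


@dataclass(frozen=True)
class GroupDelta:
    """Dark-vs-light change of one width, with its rank test."""

    group_a: GroupSummary
    group_b: GroupSummary
    mwu: MWUResult
    delta: float = field(init=False)
    percent_change: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", self.group_b.mean - self.group_a.mean)
        object.__setattr__(
            self, "percent_change", 100.0 * self.delta / self.group_a.mean
        )


def compare_groups(dark, light) -> GroupDelta:
    """Mean difference (light - dark), percent change relative to dark,
    Mann-Whitney p, and per-group summaries."""
    return GroupDelta(
        group_a=summarize(dark),
        group_b=summarize(light),
        mwu=mann_whitney(dark, light),
    )
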