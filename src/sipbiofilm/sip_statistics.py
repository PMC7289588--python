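"""Population-level delta statistics: summaries, rank tests, ellipses.

Pixel-basis statistics treat every valid pixel as one observation;
cell-basis statistics treat each segmented cell (its ratio-of-sums delta)
as a single observation.

The default two-sample comparison is the unpaired Wilcoxon rank-sum
(Mann-Whitney) test, because pixel or cell populations from two different
images are unpaired; the paired signed-rank variant is available behind
``variant="signed_rank_paired"`` for genuinely paired designs.  Results
report which variant ran.  P values below 1e-3 format as "<0.001" rather
than a literal zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (DegenerateCovarianceError, EmptyPopulationError,
                     PairingError, ValidationError)


@dataclass
class PopulationSummary:
    cls: str
    basis: str                    # "pixel" | "cell"
    n: int
    mean_delta13C: float
    sd_delta13C: float
    mean_delta15N: float
    sd_delta15N: float
    hist13C: tuple = ()           # (bin_edges, counts)
    hist15N: tuple = ()
    single_value: bool = False    # n == 1: SD reported as 0 by convention


@dataclass
class RankTestResult:
    statistic_W: float
    p_value: float
    test_variant: str             # "rank_sum_unpaired" | "signed_rank_paired"
    n1: int
    n2: int
    method: str = ""              # "exact" | "normal_approx" | "degenerate"

    @property
    def p_formatted(self) -> str:
        return "<0.001" if self.p_value < 1e-3 else f"{self.p_value:.3g}"


@dataclass
class EllipseSpec:
    center: tuple                 # (delta13C, delta15N)
    semi_axes: tuple              # (major, minor)
    rotation_rad: float           # angle of major axis from +x
    coverage: float = 0.95
    cov: np.ndarray = field(default=None, repr=False)


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=np.float64).ravel()
    return v[np.isfinite(v)]


def summarize(values13, values15, cls: str = "", basis: str = "pixel",
              bins: int = 50, hist_range13=None, hist_range15=None) -> PopulationSummary:
    """Mean, sample SD (ddof=1) and histograms for one population.

    Invalid (NaN/inf) entries are dropped first; an empty population raises
    :class:`EmptyPopulationError` naming the class and basis.  A single
    observation reports SD 0 with the ``single_value`` flag set.
    """
    v13 = _clean(values13)
    v15 = _clean(values15)
    if v13.size == 0 and v15.size == 0:
        raise EmptyPopulationError(
            f"no valid observations for class '{cls}' on basis '{basis}'"
        )
    n = int(max(v13.size, v15.size))

    def _stats(v):
        if v.size == 0:
            return np.nan, np.nan
        if v.size == 1:
            return float(v[0]), 0.0
        return float(v.mean()), float(v.std(ddof=1))

    m13, s13 = _stats(v13)
    m15, s15 = _stats(v15)
    h13 = np.histogram(v13, bins=bins, range=hist_range13) if v13.size else ()
    h15 = np.histogram(v15, bins=bins, range=hist_range15) if v15.size else ()
    return PopulationSummary(
        cls=cls, basis=basis, n=n,
        mean_delta13C=m13, sd_delta13C=s13,
        mean_delta15N=m15, sd_delta15N=s15,
        hist13C=(h13[1], h13[0]) if h13 else (),
        hist15N=(h15[1], h15[0]) if h15 else (),
        single_value=(n == 1),
    )


#: Combined sample size at or below which the rank-sum test enumerates
#: the exact null distribution (ties force the normal approximation).
EXACT_ENUMERATION_MAX_N = 25


def compare(a, b, variant: str = "rank_sum_unpaired") -> RankTestResult:
    """Two-sample rank test between delta populations.

    rank_sum_unpaired
        Mann-Whitney U (two-sided); exact enumeration when the combined
        sample size is at most :data:`EXACT_ENUMERATION_MAX_N` and the data
        carry no ties, otherwise the tie-corrected normal approximation.
    signed_rank_paired
        Wilcoxon signed-rank on element-wise differences; requires equal
        lengths.  All-zero differences are degenerate and report p = 1.
    """
    a = _clean(a)
    b = _clean(b)
    if variant == "signed_rank_paired":
        if a.size != b.size:
            raise PairingError(
                f"signed-rank pairing needs equal sample sizes "
                f"(got {a.size} and {b.size}); use variant='rank_sum_unpaired' "
                f"for independent populations"
            )
        if a.size == 0:
            raise EmptyPopulationError("empty samples for signed-rank test")
        d = a - b
        if np.all(d == 0):
            return RankTestResult(0.0, 1.0, variant, a.size, b.size,
                                  method="degenerate")
        res = stats.wilcoxon(a, b, zero_method="wilcox",
                             alternative="two-sided")
        return RankTestResult(float(res.statistic), float(res.pvalue),
                              variant, a.size, b.size, method="scipy_auto")
    if variant != "rank_sum_unpaired":
        raise ValidationError(f"unknown test variant '{variant}'")
    if a.size == 0 or b.size == 0:
        raise EmptyPopulationError("empty sample for rank-sum test")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    if a.size + b.size <= EXACT_ENUMERATION_MAX_N and no_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        method = "normal_approx"
    return RankTestResult(float(res.statistic), float(res.pvalue),
                          variant, a.size, b.size, method=method)


def ellipse_95(points) -> EllipseSpec:
    """95% coverage ellipse of bivariate (delta13C, delta15N) points.

    Built from the sample mean and covariance: semi-axes are
    sqrt(eigenvalue * q) with q the 0.95 quantile of chi-square(2 df).
    """
    pts = np.asarray(points, dtype=np.float64)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("need at least 3 finite bivariate points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * max(evals[1], 1.0):
        raise DegenerateCovarianceError(
            "points are (near-)collinear; covariance ellipse is degenerate"
        )
    q = stats.chi2.ppf(0.95, df=2)
    order = np.argsort(evals)[::-1]          # major axis first
    evals, evecs = evals[order], evecs[:, order]
    major = evecs[:, 0]
    return EllipseSpec(
        center=tuple(center),
        semi_axes=tuple(np.sqrt(evals * q)),
        rotation_rad=float(np.arctan2(major[1], major[0])),
        coverage=0.95,
        cov=cov,
    )


def ellipse_contains(spec: EllipseSpec, points) -> np.ndarray:
    """Boolean mask of points inside the ellipse (Mahalanobis test)."""
    pts = np.asarray(points, dtype=np.float64) - np.asarray(spec.center)
    inv = np.linalg.inv(spec.cov)
    d2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
    return d2 <= stats.chi2.ppf(spec.coverage, df=2)


def replicate_signature(histograms) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and SD signature across replicate image histograms.

    ``histograms`` is a list of ``(bin_edges, counts)`` pairs sharing
    identical bin edges.  Returns ``(edges, mean_counts, sd_counts)`` with
    the SD computed per bin across replicates (ddof=1; zero for a single
    replicate).
    """
    if not histograms:
        raise EmptyPopulationError("no replicate histograms supplied")
    edges0 = np.asarray(histograms[0][0], dtype=np.float64)
    counts = []
    for edges, c in histograms:
        if not np.array_equal(np.asarray(edges, dtype=np.float64), edges0):
            raise ValidationError("replicate histograms must share bin edges")
        counts.append(np.asarray(c, dtype=np.float64))
    arr = np.vstack(counts)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros_like(mean)
    return edges0, mean, sd
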