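"""Isotope ratios, atom fractions and delta (per-mil) enrichment maps.

Isotope content is expressed in standard delta notation,

    delta = (R_sample / R_standard - 1) * 1000 [permil]

with 13C referenced to VPDB (R = 0.0112372) and 15N to atmospheric N2
(AIR, R = 0.003676).

Count-to-ratio conventions
--------------------------
The C2- isotopologue pair measures carbon through diatomic ions.  Under
random (binomial) isotope pairing, and neglecting the doubly heavy 13C13C-
species (second order in the atom fraction), the count ratio
12C13C-/12C12C- equals 2x/(1-x), so halving it yields the atomic 13C/12C
ratio x/(1-x) exactly.  This factor-1/2 correction is applied by default;
``c2_correction="none"`` reports the raw count ratio instead.  The CN- pair
carries a single nitrogen atom, so 12C15N-/12C14N- is already the atomic
15N/14N ratio and no factor is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError, ValidationError
from .ion_stack_io import SummedImage

#: 13C/12C of Vienna Pee Dee Belemnite.
R_VPDB_13C = 0.0112372
#: 15N/14N of atmospheric N2.
R_AIR_15N = 0.003676

_C2_CORRECTIONS = ("half", "none")


@dataclass(frozen=True)
class ReferenceRatios:
    """International reference isotope ratios used for delta conversion."""

    R_standard_13C: float = R_VPDB_13C
    R_standard_15N: float = R_AIR_15N
    permil_scale: float = 1000.0

    def __post_init__(self):
        if self.R_standard_13C <= 0 or self.R_standard_15N <= 0:
            raise ValidationError("reference ratios must be positive")


@dataclass
class EnrichmentMaps:
    """Per-pixel delta13C / delta15N images with validity masking.

    Invalid pixels (denominator isotopologue below ``min_counts_used``)
    carry NaN deltas.  ``valid`` is the conjunction of the per-isotope
    validity masks ``valid13`` and ``valid15``.
    """

    delta13C: np.ndarray
    delta15N: np.ndarray
    R13: np.ndarray
    R15: np.ndarray
    valid13: np.ndarray
    valid15: np.ndarray
    references: ReferenceRatios
    min_counts_used: int

    @property
    def valid(self) -> np.ndarray:
        return self.valid13 & self.valid15


def ratio_from_c2_counts(c_12c13c, c_12c12c, c2_correction: str = "half"):
    """13C/12C atom ratio from the C2- isotopologue pair.

    Pixels (or scalars) with a non-positive denominator yield NaN rather
    than raising, so the bulk image path can mask them.
    """
    if c2_correction not in _C2_CORRECTIONS:
        raise ValidationError(f"c2_correction must be one of {_C2_CORRECTIONS}")
    num = np.asarray(c_12c13c, dtype=np.float64)
    den = np.asarray(c_12c12c, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    if c2_correction == "half":
        r = r / 2.0
    return r if r.ndim else float(r)


def ratio_from_cn_counts(c_12c15n, c_12c14n):
    """15N/14N atom ratio from the CN- isotopologue pair (no factor)."""
    num = np.asarray(c_12c15n, dtype=np.float64)
    den = np.asarray(c_12c14n, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return r if r.ndim else float(r)


def delta_from_ratio(R_sample, R_standard: float):
    """Delta value in permil for a sample ratio against a reference ratio."""
    if R_standard <= 0:
        raise ValidationError("R_standard must be positive")
    r = np.asarray(R_sample, dtype=np.float64)
    if np.any(r[~np.isnan(r)] < 0):
        raise ValidationError("R_sample must be non-negative")
    d = (r / R_standard - 1.0) * 1000.0
    return d if d.ndim else float(d)


def atom_fraction_from_delta(delta, R_standard: float):
    """Heavy-isotope atom fraction x = R/(1+R) implied by a delta value."""
    d = np.asarray(delta, dtype=np.float64)
    if np.any(d[~np.isnan(d)] < -1000.0):
        raise ValidationError("delta below -1000 permil implies a negative ratio")
    R = R_standard * (1.0 + d / 1000.0)
    x = R / (1.0 + R)
    return x if x.ndim else float(x)


def delta_from_atom_fraction(x, R_standard: float):
    """Inverse of :func:`atom_fraction_from_delta`."""
    xa = np.asarray(x, dtype=np.float64)
    if np.any((xa < 0) | (xa >= 1)):
        raise ValidationError("atom fraction must lie in [0, 1)")
    R = xa / (1.0 - xa)
    return delta_from_ratio(R, R_standard)


def enrichment_maps(
    summed: SummedImage,
    refs: ReferenceRatios = ReferenceRatios(),
    min_counts: int = 100,
    c2_correction: str = "half",
) -> EnrichmentMaps:
    """Per-pixel delta13C and delta15N maps from a plane-summed image.

    Ratios are formed from summed counts (ratio-of-sums, never a mean of
    per-plane ratios).  A pixel is valid for an isotope only when its
    denominator isotopologue (12C12C- resp. 12C14N-) reaches ``min_counts``;
    the default of 100 keeps the Poisson standard error of delta below
    roughly 100 permil at natural abundance.
    """
    for name in ("12C12C", "12C13C", "12C14N", "12C15N"):
        if name not in summed.channel_names:
            raise FormatError(f"summed image lacks isotopologue channel '{name}'")
    c12 = summed.channel("12C12C")
    c13 = summed.channel("12C13C")
    n14 = summed.channel("12C14N")
    n15 = summed.channel("12C15N")

    valid13 = c12 >= max(min_counts, 1)
    valid15 = n14 >= max(min_counts, 1)

    R13 = ratio_from_c2_counts(c13, c12, c2_correction=c2_correction)
    R15 = ratio_from_cn_counts(n15, n14)
    d13 = np.where(valid13, delta_from_ratio(np.nan_to_num(R13), refs.R_standard_13C), np.nan)
    d15 = np.where(valid15, delta_from_ratio(np.nan_to_num(R15), refs.R_standard_15N), np.nan)
    R13 = np.where(valid13, R13, np.nan)
    R15 = np.where(valid15, R15, np.nan)

    return EnrichmentMaps(
        delta13C=d13,
        delta15N=d15,
        R13=R13,
        R15=R15,
        valid13=valid13,
        valid15=valid15,
        references=refs,
        min_counts_used=int(min_counts),
    )


def pooled_delta(
    numerator_counts: np.ndarray,
    denominator_counts: np.ndarray,
    R_standard: float,
    c2_correction: str | None = None,
) -> tuple[float, float]:
    """Delta of a pixel population from pooled (summed) counts, with its SE.

    Returns ``(delta, se_delta)`` where the standard error propagates the
    Poisson variance of both summed isotopologue counts.  ``c2_correction``
    set to ``"half"`` applies the diatomic factor (use for the C2- pair).
    """
    S_num = float(np.sum(numerator_counts))
    S_den = float(np.sum(denominator_counts))
    if S_den <= 0 or S_num < 0:
        raise ValidationError("pooled counts must have a positive denominator")
    r = S_num / S_den
    if c2_correction == "half":
        r = r / 2.0
    delta = (r / R_standard - 1.0) * 1000.0
    rel_var = (1.0 / S_num if S_num > 0 else 0.0) + 1.0 / S_den
    se = (r / R_standard) * 1000.0 * np.sqrt(rel_var)
    return delta, se
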