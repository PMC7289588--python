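"""Bulk assays: IRMS two-point delta calibration, qPCR genome counting,
and proteomic peptide-count normalization.

IRMS calibration
----------------
Measured bulk delta values are recalibrated with a two-point (affine)
correction anchored on two certified standards (defaults: USGS 40,
delta13C = -26.39 permil, and USGS 41, +37.63 permil).  Standards that run
immediately after a highly enriched sample are screened for carryover:
if such a measurement deviates from the running mean of the previously
accepted measurements of the same standard by more than a tolerance
(default 2 permil) it is flagged and excluded from the fit — flagged
standards are reported, never silently dropped.  delta15N calibration uses
the same machinery with AIR-referenced anchors.

qPCR
----
Genomes are counted against a standard curve of Cq versus log10(copies)
(the study design: decade standards 3x10^1..3x10^6, assayed in triplicate,
targeting the single-copy rpoC gene so copies = genomes).  Technical
triplicates are averaged per copy level before the least-squares fit.
Amplification efficiency derives from the slope as 10^(-1/slope) - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, FitError, ValidationError

USGS40_DELTA13C = -26.39
USGS41_DELTA13C = +37.63


@dataclass
class IrmsRecord:
    sample_id: str
    kind: str                      # "sample" | "standard"
    measured_delta: float          # permil
    run_position: int
    assigned_delta: float | None = None   # permil; required for standards
    follows_labeled: bool = False

    def __post_init__(self):
        if self.kind not in ("sample", "standard"):
            raise ValidationError(f"unknown record kind '{self.kind}'")
        if self.kind == "standard" and self.assigned_delta is None:
            raise ValidationError(
                f"standard '{self.sample_id}' lacks an assigned delta"
            )


@dataclass
class CalibrationReport:
    slope: float
    intercept: float
    anchor_assigned: tuple         # (low, high) assigned deltas
    anchor_measured_means: tuple   # measured means used for the fit
    flagged_carryover: list        # sample_ids excluded from the fit
    tolerance: float
    n_standards_used: int


def two_point_correct(records: list, tolerance: float = 2.0
                      ) -> tuple[pd.DataFrame, CalibrationReport]:
    """Carryover-screen the standards, fit the affine map, correct all records.

    Returns ``(table, report)`` where the table has one row per input record
    with a ``corrected_delta`` column.  Anchor measurements reproduce their
    assigned values exactly (up to the spread of replicate anchors).
    """
    recs = sorted(records, key=lambda r: r.run_position)
    positions = [r.run_position for r in recs]
    if len(set(positions)) != len(positions):
        raise ValidationError("run positions must be unique within a run")

    # carryover screening per assigned-standard group, in run order; a
    # standard with no prior clean measurement is screened against its
    # assigned value instead of a running mean
    flagged: list[str] = []
    clean: dict[float, list[float]] = {}
    for r in recs:
        if r.kind != "standard":
            continue
        group = clean.setdefault(r.assigned_delta, [])
        if r.follows_labeled:
            baseline = np.mean(group) if group else r.assigned_delta
            if abs(r.measured_delta - baseline) > tolerance:
                flagged.append(r.sample_id)
                continue
        group.append(r.measured_delta)

    anchors = {a: vals for a, vals in clean.items() if vals}
    if len(anchors) < 2:
        raise CalibrationError(
            "fewer than 2 clean standard anchors remain after carryover "
            f"screening (flagged: {flagged or 'none'})"
        )
    lo_a, hi_a = min(anchors), max(anchors)
    lo_m = float(np.mean(anchors[lo_a]))
    hi_m = float(np.mean(anchors[hi_a]))
    if hi_m == lo_m:
        raise CalibrationError("anchor measured means coincide; cannot fit")
    slope = (hi_a - lo_a) / (hi_m - lo_m)
    intercept = lo_a - slope * lo_m

    rows = []
    for r in recs:
        rows.append({
            "sample_id": r.sample_id,
            "kind": r.kind,
            "run_position": r.run_position,
            "assigned_delta": r.assigned_delta,
            "measured_delta": r.measured_delta,
            "follows_labeled": r.follows_labeled,
            "carryover_flagged": r.sample_id in flagged,
            "corrected_delta": slope * r.measured_delta + intercept,
        })
    report = CalibrationReport(
        slope=slope, intercept=intercept,
        anchor_assigned=(lo_a, hi_a),
        anchor_measured_means=(lo_m, hi_m),
        flagged_carryover=flagged,
        tolerance=tolerance,
        n_standards_used=sum(len(v) for v in anchors.values()),
    )
    return pd.DataFrame(rows), report


# ---------------------------------------------------------------------------
# qPCR

#: Copy numbers of the per-plate decade standard series.
STANDARD_CURVE_COPIES = (3e1, 3e2, 3e3, 3e4, 3e5, 3e6)


@dataclass
class StandardCurve:
    slope: float                   # Cq per log10(copies); negative
    intercept: float               # Cq at 1 copy
    efficiency: float              # 10^(-1/slope) - 1
    r_squared: float
    points: list = field(default_factory=list)   # (copies, mean Cq)


def fit_standard_curve(points) -> StandardCurve:
    """Least-squares Cq ~ log10(copies) fit.

    ``points`` is an iterable of ``(copies, Cq)`` pairs (technical
    replicates allowed; they are averaged per copy level first).
    """
    df = pd.DataFrame(list(points), columns=["copies", "cq"])
    if np.any(df["copies"] <= 0):
        raise ValidationError("standard copies must be positive")
    if not np.all(np.isfinite(df["cq"])):
        raise ValidationError("standard Cq values must be finite")
    by_level = df.groupby("copies", as_index=False)["cq"].mean()
    if len(by_level) < 3:
        raise ValidationError("need >= 3 distinct copy levels for a curve")
    x = np.log10(by_level["copies"].to_numpy())
    y = by_level["cq"].to_numpy()
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise FitError(
            "standard-curve slope is non-negative; Cq should decrease with "
            "copies (inputs may be inverted)"
        )
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(10.0 ** (-1.0 / res.slope) - 1.0),
        r_squared=float(res.rvalue ** 2),
        points=list(zip(by_level["copies"], by_level["cq"])),
    )


def quantify(curve: StandardCurve, cq) -> np.ndarray:
    """Invert the standard curve: copies = 10^((Cq - intercept)/slope)."""
    cq = np.asarray(cq, dtype=np.float64)
    out = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return out if out.ndim else float(out)


def relative_abundance(copies: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate relative abundances with Welch's t test per member.

    ``copies`` needs columns ``member``, ``condition``, ``replicate``,
    ``copies``.  Relative abundances are normalized within each
    (condition, replicate); Welch's unequal-variance t test compares each
    member's relative abundance between the two conditions (two-sided).
    With a single replicate in either condition the abundances are still
    computed but the test is skipped with a warning.
    """
    required = {"member", "condition", "replicate", "copies"}
    if not required.issubset(copies.columns):
        raise ValidationError(f"copies table needs columns {sorted(required)}")
    df = copies.copy()
    totals = df.groupby(["condition", "replicate"])["copies"].transform("sum")
    df["relative_abundance"] = df["copies"] / totals
    conditions = sorted(df["condition"].unique())
    if len(conditions) != 2:
        raise ValidationError("relative_abundance expects exactly 2 conditions")
    rows = []
    for member, g in df.groupby("member"):
        a = g.loc[g["condition"] == conditions[0], "relative_abundance"].to_numpy()
        b = g.loc[g["condition"] == conditions[1], "relative_abundance"].to_numpy()
        t = p = np.nan
        if min(a.size, b.size) < 2:
            warnings.warn(
                f"member '{member}': fewer than 2 replicates in a condition; "
                "Welch test skipped", stacklevel=2)
        elif np.array_equal(np.sort(a), np.sort(b)) and a.std() == 0 and b.std() == 0:
            t, p = 0.0, 1.0   # identical, zero-variance conditions
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
            if np.isnan(t) and np.isclose(a.mean(), b.mean()):
                t, p = 0.0, 1.0
        rows.append({"member": member,
                     f"mean_{conditions[0]}": a.mean() if a.size else np.nan,
                     f"mean_{conditions[1]}": b.mean() if b.size else np.nan,
                     "welch_t": t, "p_value": p})
    result = df.merge(pd.DataFrame(rows), on="member")
    return result


# ---------------------------------------------------------------------------
# Proteomics

def normalize_peptides(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize peptide counts by per-organism totals.

    ``counts`` needs columns ``organism``, ``protein``, ``sample``,
    ``count``.  Adds ``fraction_of_organism`` (a protein's share of its
    organism's total counts in that sample; NaN when the organism has zero
    total) and ``organism_share`` (the organism's share of all counts in
    the sample).
    """
    required = {"organism", "protein", "sample", "count"}
    if not required.issubset(counts.columns):
        raise ValidationError(f"counts table needs columns {sorted(required)}")
    if np.any(counts["count"] < 0):
        raise ValidationError("peptide counts must be non-negative")
    df = counts.copy()
    org_tot = df.groupby(["organism", "sample"])["count"].transform("sum")
    with np.errstate(invalid="ignore"):
        df["fraction_of_organism"] = np.where(
            org_tot > 0, df["count"] / org_tot.replace(0, np.nan), np.nan)
    grand = df.groupby("sample")["count"].transform("sum")
    df["organism_share"] = org_tot / grand
    return df
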