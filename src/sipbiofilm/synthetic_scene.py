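"""Synthetic biofilm scenes with known ground truth, and assay fixtures.

The generator emulates the study's acquisition geometry — 40 um x 40 um
fields at 256 x 256 pixels, 2 ms/pixel, ~13 planes — and the two labeling
regimes (NO3- only vs NH4+ amended).  A scene is a set of filamentous
autotrophs (constant-width tubes along random cubic splines, each filament
one connected component) with coccoid heterotrophs partly attached to
filament flanks and partly distal, plus small phosphate-granule subregions
inside the filaments that elevate the 31P- rate.

Class isotopic compositions default to the per-condition population delta
values the study reports for heterotrophs (NO3-only: delta13C 1328.39,
delta15N 1814.13 permil; NH4-amended: delta13C 121.38, delta15N 6351.97
permil), with autotrophs co-enriched in both isotopes under both conditions
and more strongly under NH4+ amendment.  These are generator parameters
that set the ground truth, not claims about any particular dataset.  The
per-class channel count rates are invented (no intensity values are
published); they are chosen so that biomass CN- signal exceeds background
by well over 10x, which makes thresholding well-posed.

Rendering draws, per plane and pixel, the total C2- count from a Poisson
law and splits it into 12C12C- and 12C13C- binomially with heavy-isotope
probability 2x/(1+x) (random isotope pairing with the doubly heavy 13C13C-
isotopologue neglected — an error second order in x13); the CN- pair splits
by (1-x15) vs x15; 16O- and 31P- are plain Poisson draws at class rates.

Every operation draws from its own pseudo-random stream seeded from the
scene seed plus an operation tag, so adding objects never perturbs
unrelated draws.  Identical seed and spec reproduce scenes and stacks
bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from skimage.draw import disk as draw_disk

from .bulk_assays import (IrmsRecord, STANDARD_CURVE_COPIES, USGS40_DELTA13C,
                          USGS41_DELTA13C)
from .enrichment import R_AIR_15N, R_VPDB_13C, atom_fraction_from_delta
from .errors import PlacementError, ValidationError
from .ion_stack_io import CHANNELS, IonImageStack

CONDITIONS = ("NO3_only", "NH4_amended")

# operation tags for independent random streams
_TAG_SCENE = 1
_TAG_RENDER = 2
_TAG_BULK = 3
_TAG_QPCR = 4
_TAG_PEPTIDE = 5


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and acquisition parameters of a synthetic scene."""

    image_height_px: int = 256
    image_width_px: int = 256
    pixel_size_um: float = 40.0 / 256.0
    n_planes: int = 13
    n_filaments: int = 2
    n_cocci: int = 30
    filament_width_px: float = 9.0
    coccus_radius_px: float = 3.0
    seed: int = 0
    condition_tag: str = "NO3_only"
    dwell_time_ms_per_px: float = 2.0

    def __post_init__(self):
        if self.image_height_px < 16 or self.image_width_px < 16:
            raise ValidationError("scene dimensions must be >= 16 px")
        if self.n_planes < 1:
            raise ValidationError("n_planes must be >= 1")
        if self.n_filaments < 0 or self.n_cocci < 0:
            raise ValidationError("object counts must be non-negative")
        if self.filament_width_px <= 0 or self.coccus_radius_px <= 0:
            raise ValidationError("object sizes must be positive")
        if self.condition_tag not in CONDITIONS:
            raise ValidationError(f"condition_tag must be one of {CONDITIONS}")


@dataclass(frozen=True)
class ClassLabelProfile:
    """Isotopic composition and channel count rates for one scene class.

    ``channel_rates`` gives expected counts per pixel per plane for the
    16O-, total C2-, total CN- and 31P- channels.  ``granule_rate_31P`` is
    the extra 31P- rate inside phosphate granules (autotrophs only).
    """

    cls: str                        # "autotroph" | "heterotroph" | "background"
    x13: float
    x15: float
    channel_rates: dict             # {"16O":, "C2":, "CN":, "31P":}
    granule_rate_31P: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.x13 <= 1.0 and 0.0 <= self.x15 <= 1.0):
            raise ValidationError("atom fractions must lie in [0, 1]")
        if any(v < 0 for v in self.channel_rates.values()):
            raise ValidationError("channel rates must be non-negative")


@dataclass
class GroundTruth:
    """Per-pixel ground truth of a synthetic scene.

    ``class_map`` uses 0 = background, 1 = autotroph, 2 = heterotroph;
    overlapping heterotroph/autotroph pixels are resolved in favor of the
    autotroph but the full pre-resolution coccus footprint is recorded in
    ``heterotroph_footprint`` so overlap-exclusion logic stays testable.
    """

    class_map: np.ndarray
    x13_map: np.ndarray
    x15_map: np.ndarray
    cell_id_map: np.ndarray
    granule_mask: np.ndarray
    heterotroph_footprint: np.ndarray
    n_filaments: int = 0
    n_cocci: int = 0

    CLASS_CODES = {"background": 0, "autotroph": 1, "heterotroph": 2}

    def class_mask(self, cls: str) -> np.ndarray:
        return self.class_map == self.CLASS_CODES[cls]


# ---------------------------------------------------------------------------
# Default condition profiles

#: Per-condition (delta13C, delta15N) targets in permil used as generator
#: ground truth.  Heterotroph values are the study's printed population
#: means; autotroph values are qualitative (co-enriched, higher under NH4+).
DELTA_TARGETS = {
    "NO3_only": {"heterotroph": (1328.39, 1814.13),
                 "autotroph": (4000.0, 9000.0),
                 "background": (0.0, 0.0)},
    "NH4_amended": {"heterotroph": (121.38, 6351.97),
                    "autotroph": (6000.0, 20000.0),
                    "background": (0.0, 0.0)},
}

#: Invented per-class expected counts per pixel per plane (none published).
DEFAULT_CHANNEL_RATES = {
    "background": {"16O": 2.0, "C2": 0.5, "CN": 1.0, "31P": 0.05},
    "autotroph": {"16O": 30.0, "C2": 45.0, "CN": 150.0, "31P": 8.0},
    "heterotroph": {"16O": 25.0, "C2": 40.0, "CN": 120.0, "31P": 0.2},
}

#: Extra 31P- rate inside phosphate granules (invented).
DEFAULT_GRANULE_RATE_31P = 50.0


def default_profiles(condition: str) -> dict:
    """Class profiles whose deltas match the per-condition targets."""
    if condition not in CONDITIONS:
        raise ValidationError(f"condition must be one of {CONDITIONS}")
    profiles = {}
    for cls, (d13, d15) in DELTA_TARGETS[condition].items():
        profiles[cls] = ClassLabelProfile(
            cls=cls,
            x13=atom_fraction_from_delta(d13, R_VPDB_13C),
            x15=atom_fraction_from_delta(d15, R_AIR_15N),
            channel_rates=dict(DEFAULT_CHANNEL_RATES[cls]),
            granule_rate_31P=(DEFAULT_GRANULE_RATE_31P
                              if cls == "autotroph" else 0.0),
        )
    return profiles


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), tag]))


# ---------------------------------------------------------------------------
# Scene construction

def _stamp_disk(mask: np.ndarray, center, radius: float) -> None:
    rr, cc = draw_disk(center, radius, shape=mask.shape)
    mask[rr, cc] = True


def _draw_filament(shape, rng, width_px: float) -> tuple[np.ndarray, np.ndarray]:
    """One constant-width tube along a random horizontal cubic spline.

    Returns (mask, centerline) with centerline as an (n, 2) float array of
    (row, col) samples.
    """
    h, w = shape
    half = width_px / 2.0
    margin = half + 1.0
    if h - 2 * margin < 1:
        raise PlacementError(
            f"filament of width {width_px} px does not fit a {h}-px-tall canvas"
        )
    n_ctrl = 5
    xs = np.linspace(0.0, w - 1.0, n_ctrl)
    ys = rng.uniform(margin, h - 1.0 - margin, size=n_ctrl)
    spline = CubicSpline(xs, ys)
    t = np.linspace(0.0, w - 1.0, 4 * w)
    yy = np.clip(spline(t), margin, h - 1.0 - margin)
    mask = np.zeros(shape, dtype=bool)
    for r, c in zip(yy, t):
        _stamp_disk(mask, (r, c), half)
    return mask, np.column_stack([yy, t])


def _place_cocci(shape, rng, n_cocci, radius, filament_mask, centerlines,
                 filament_half_width):
    """Coccus centers: half side-attached to filament flanks, half distal."""
    h, w = shape
    if 2 * radius + 2 > min(h, w):
        raise PlacementError(
            f"coccus of radius {radius} px does not fit a {h}x{w} canvas"
        )
    from scipy import ndimage as ndi
    dist_to_filament = (ndi.distance_transform_edt(~filament_mask)
                        if filament_mask.any() else None)
    centers: list[tuple[float, float]] = []

    def clashes(center):
        return any(np.hypot(center[0] - c[0], center[1] - c[1]) < 2 * radius + 2
                   for c in centers)

    def inside(center):
        return (radius <= center[0] <= h - 1 - radius
                and radius <= center[1] <= w - 1 - radius)

    def mostly_visible(center):
        # a side-attached cell must stay beside the filament, not under it;
        # high-curvature sections can otherwise swallow the whole disc
        disc = np.zeros(shape, dtype=bool)
        _stamp_disk(disc, center, radius)
        return (disc & ~filament_mask).sum() >= 0.6 * disc.sum()

    n_attached = n_cocci // 2 if centerlines else 0
    for i in range(n_cocci):
        attached = i < n_attached
        placed = False
        for _ in range(400):
            if attached:
                line = centerlines[rng.integers(len(centerlines))]
                k = rng.integers(1, len(line) - 1)
                tangent = line[k + 1] - line[k - 1]
                normal = np.array([-tangent[1], tangent[0]])
                normal /= max(np.hypot(*normal), 1e-9)
                side = rng.choice([-1.0, 1.0])
                center = line[k] + side * normal * (filament_half_width + radius - 1.0)
                center = (float(center[0]), float(center[1]))
                if not mostly_visible(center):
                    continue
            else:
                center = (float(rng.uniform(radius, h - 1 - radius)),
                          float(rng.uniform(radius, w - 1 - radius)))
                if dist_to_filament is not None:
                    r0, c0 = int(round(center[0])), int(round(center[1]))
                    if dist_to_filament[r0, c0] < radius + 3:
                        continue
            if inside(center) and not clashes(center):
                centers.append(center)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place coccus {i + 1}/{n_cocci} "
                f"({'side-attached' if attached else 'distal'}) on a "
                f"{h}x{w} canvas"
            )
    return centers


def make_scene(spec: SceneSpec, profiles: dict | None = None) -> GroundTruth:
    """Generate a ground-truth scene for the spec's condition.

    ``profiles`` maps class name to :class:`ClassLabelProfile` and must
    cover background, autotroph and heterotroph (defaults to the condition's
    default profiles).
    """
    profiles = profiles or default_profiles(spec.condition_tag)
    missing = {"background", "autotroph", "heterotroph"} - set(profiles)
    if missing:
        raise ValidationError(f"profiles missing classes: {sorted(missing)}")
    rng = _rng(spec.seed, _TAG_SCENE)
    shape = (spec.image_height_px, spec.image_width_px)

    filament_union = np.zeros(shape, dtype=bool)
    cell_id_map = np.zeros(shape, dtype=np.int32)
    centerlines = []
    for fid in range(1, spec.n_filaments + 1):
        mask, line = _draw_filament(shape, rng, spec.filament_width_px)
        # later filaments may cross earlier ones; ids overwrite where they do
        cell_id_map[mask] = fid
        filament_union |= mask
        centerlines.append(line)

    granule_mask = np.zeros(shape, dtype=bool)
    for line in centerlines:
        n_granules = max(1, len(line) // 400)
        for k in rng.choice(len(line), size=n_granules, replace=False):
            _stamp_disk(granule_mask, tuple(line[k]), 2.0)
    granule_mask &= filament_union

    centers = _place_cocci(shape, rng, spec.n_cocci, spec.coccus_radius_px,
                           filament_union, centerlines,
                           spec.filament_width_px / 2.0)
    het_footprint = np.zeros(shape, dtype=bool)
    class_map = np.where(filament_union, 1, 0).astype(np.int8)
    for j, center in enumerate(centers, start=spec.n_filaments + 1):
        coccus = np.zeros(shape, dtype=bool)
        _stamp_disk(coccus, center, spec.coccus_radius_px)
        het_footprint |= coccus
        visible = coccus & ~filament_union   # autotroph wins overlaps
        class_map[visible] = 2
        cell_id_map[visible] = j

    x13_map = np.zeros(shape, dtype=np.float64)
    x15_map = np.zeros(shape, dtype=np.float64)
    for cls, code in GroundTruth.CLASS_CODES.items():
        sel = class_map == code
        x13_map[sel] = profiles[cls].x13
        x15_map[sel] = profiles[cls].x15

    return GroundTruth(
        class_map=class_map,
        x13_map=x13_map,
        x15_map=x15_map,
        cell_id_map=cell_id_map,
        granule_mask=granule_mask,
        heterotroph_footprint=het_footprint,
        n_filaments=spec.n_filaments,
        n_cocci=spec.n_cocci,
    )


# ---------------------------------------------------------------------------
# Ion-count rendering

def heavy_fraction_c2(x13):
    """Probability that a C2- ion is the 12C13C- isotopologue.

    Random pairing gives species weights (1-x)^2 : 2x(1-x) (13C13C-
    neglected), hence P(12C13C-) = 2x/(1+x).
    """
    x = np.asarray(x13, dtype=np.float64)
    return 2.0 * x / (1.0 + x)


def render_ion_counts(truth: GroundTruth, spec: SceneSpec,
                      profiles: dict | None = None,
                      seed: int | None = None) -> IonImageStack:
    """Render a ground-truth scene into a noisy multi-channel count stack."""
    profiles = profiles or default_profiles(spec.condition_tag)
    rng = _rng(spec.seed if seed is None else seed, _TAG_RENDER)
    shape = truth.class_map.shape

    rates = {key: np.zeros(shape) for key in ("16O", "C2", "CN", "31P")}
    for cls, code in GroundTruth.CLASS_CODES.items():
        sel = truth.class_map == code
        for key in rates:
            rates[key][sel] = profiles[cls].channel_rates[key]
    rates["31P"][truth.granule_mask] += profiles["autotroph"].granule_rate_31P

    p13 = heavy_fraction_c2(truth.x13_map)
    p15 = truth.x15_map
    planes = []
    for _ in range(spec.n_planes):
        o16 = rng.poisson(rates["16O"])
        c2_tot = rng.poisson(rates["C2"])
        c13 = rng.binomial(c2_tot, p13)
        c12 = c2_tot - c13
        cn_tot = rng.poisson(rates["CN"])
        n15 = rng.binomial(cn_tot, p15)
        n14 = cn_tot - n15
        p31 = rng.poisson(rates["31P"])
        planes.append(np.stack([o16, c12, c13, n14, n15, p31]))
    counts = np.stack(planes).astype(np.uint32)
    return IonImageStack(
        counts=counts,
        channel_names=CHANNELS,
        pixel_size_um=spec.pixel_size_um,
        dwell_time_ms_per_px=spec.dwell_time_ms_per_px,
        acquisition_tag=f"synthetic:{spec.condition_tag}:seed={spec.seed}",
    )


def simulate_stack(spec: SceneSpec, profiles: dict | None = None
                   ) -> tuple[GroundTruth, IonImageStack]:
    """Convenience: scene + rendered stack under the spec's condition."""
    profiles = profiles or default_profiles(spec.condition_tag)
    truth = make_scene(spec, profiles)
    return truth, render_ion_counts(truth, spec, profiles)


# ---------------------------------------------------------------------------
# Bulk fixtures

def make_bulk_fixture(n_samples: int, true_deltas, calibration_offsets=(1.0, 0.0),
                      seed: int = 0, noise_sd: float = 0.0,
                      anchors=(USGS40_DELTA13C, USGS41_DELTA13C),
                      carryover_shift: float = 0.0) -> list:
    """Synthetic IRMS run: bracketing standards plus samples.

    Measured deltas are an affine distortion of the true values,
    ``measured = slope * true + intercept`` with ``calibration_offsets =
    (slope, intercept)``, plus Gaussian noise.  With ``carryover_shift``
    nonzero, an extra post-labeled-sample standard is appended whose
    measurement is inflated by that many permil and flagged
    ``follows_labeled`` — fodder for the carryover screen.
    """
    true_deltas = np.asarray(true_deltas, dtype=np.float64)
    if true_deltas.size != n_samples:
        raise ValidationError("true_deltas length must equal n_samples")
    slope, intercept = calibration_offsets
    rng = _rng(seed, _TAG_BULK)

    def measure(true):
        return slope * true + intercept + (rng.normal(0.0, noise_sd)
                                           if noise_sd > 0 else 0.0)

    records, pos = [], 0
    for i, a in enumerate(anchors):
        records.append(IrmsRecord(f"std_pre_{i}", "standard", measure(a), pos,
                                  assigned_delta=a))
        pos += 1
    for i in range(n_samples):
        records.append(IrmsRecord(f"sample_{i}", "sample",
                                  measure(true_deltas[i]), pos))
        pos += 1
    for i, a in enumerate(anchors):
        records.append(IrmsRecord(f"std_post_{i}", "standard", measure(a), pos,
                                  assigned_delta=a))
        pos += 1
    if carryover_shift != 0.0:
        records.append(IrmsRecord("sample_hot", "sample", measure(5000.0), pos))
        pos += 1
        records.append(IrmsRecord("std_carryover", "standard",
                                  measure(anchors[0]) + carryover_shift, pos,
                                  assigned_delta=anchors[0],
                                  follows_labeled=True))
    return records


def make_qpcr_fixture(true_copies, efficiency: float = 1.0, seed: int = 0,
                      noise_sd: float = 0.0, intercept: float = 38.0,
                      n_replicates: int = 3) -> tuple:
    """Synthetic qPCR plate: decade standards in triplicate plus unknowns.

    Cq = intercept - log10(copies) * ln(10)/ln(1 + efficiency) + noise;
    at 100% efficiency adjacent decades are log2(10) = 3.3219 cycles apart.
    Returns ``(standards, unknowns)`` DataFrames; unknowns carry their true
    copy numbers for round-trip checks.
    """
    if not (0.5 < efficiency <= 1.1):
        raise ValidationError("efficiency must lie in (0.5, 1.1]")
    true_copies = dict(true_copies)
    if any(v <= 0 for v in true_copies.values()):
        raise ValidationError("copies must be positive")
    rng = _rng(seed, _TAG_QPCR)
    slope = -np.log(10.0) / np.log(1.0 + efficiency)

    def cq_of(copies):
        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        return intercept + slope * np.log10(copies) + noise

    std_rows = [{"copies": c, "replicate": rep, "cq": cq_of(c)}
                for c in STANDARD_CURVE_COPIES
                for rep in range(n_replicates)]
    unk_rows = [{"sample_id": name, "replicate": rep, "cq": cq_of(c),
                 "true_copies": c}
                for name, c in true_copies.items()
                for rep in range(n_replicates)]
    return pd.DataFrame(std_rows), pd.DataFrame(unk_rows)


def make_peptide_fixture(organism_sizes, seed: int = 0,
                         sample: str = "S1") -> pd.DataFrame:
    """Synthetic peptide-count table, multinomial per organism.

    ``organism_sizes`` maps organism -> (n_proteins, total_peptides); each
    organism's total is spread over its proteins by a multinomial draw with
    Dirichlet(1) protein weights.
    """
    rng = _rng(seed, _TAG_PEPTIDE)
    rows = []
    for organism, (n_proteins, total) in dict(organism_sizes).items():
        if n_proteins < 1 or total < 0:
            raise ValidationError("need >= 1 protein and non-negative totals")
        probs = rng.dirichlet(np.ones(n_proteins))
        counts = rng.multinomial(int(total), probs)
        for k, c in enumerate(counts):
            rows.append({"organism": organism, "protein": f"{organism}_p{k}",
                         "sample": sample, "count": int(c)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ground-truth serialization (integer-label TIFF + JSON sidecar)

def write_ground_truth(truth: GroundTruth, spec: SceneSpec, directory) -> None:
    from pathlib import Path
    import tifffile
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "class_map.tif", truth.class_map.astype(np.int32))
    tifffile.imwrite(directory / "cell_id_map.tif", truth.cell_id_map.astype(np.int32))
    tifffile.imwrite(directory / "granule_mask.tif",
                     truth.granule_mask.astype(np.uint8))
    np.savez_compressed(directory / "atom_fractions.npz",
                        x13_map=truth.x13_map, x15_map=truth.x15_map)
    sidecar = {
        "spec": asdict(spec),
        "class_codes": GroundTruth.CLASS_CODES,
        "n_filaments": truth.n_filaments,
        "n_cocci": truth.n_cocci,
    }
    (directory / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
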