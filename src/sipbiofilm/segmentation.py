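"""Autotroph / heterotroph segmentation of summed ion images.

The classes are separated from the 16O-, 12C14N- and 31P- channels by
log-transforming each channel, thresholding it (automatic Otsu threshold on
the log image by default, manual override available), combining the three
binary masks through a boolean recipe, morphological cleanup, and an
overlap-exclusion step: heterotroph blobs lying on top of the cyanobacterial
filaments are discarded while side-attached cells are kept.

The default recipe treats elevated 31P- as the autotroph marker::

    biomass        = cn
    autotroph      = cn & p
    heterotroph    = cn & ~p
    background     = ~(cn | o)
    phosphate_high = p & ~cn

The recipe is a user-overridable set of boolean expressions over the input
mask names ``o``, ``cn``, ``p`` (plus ``biomass``) and is stored in the
output for provenance; it is a stated assumption, not a fixed truth about
any particular instrument or community.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import footprint_rectangle, opening, remove_small_objects

from .enrichment import EnrichmentMaps
from .errors import ConfigError, ThresholdError, ValidationError
from .ion_stack_io import SummedImage

DEFAULT_RECIPE = {
    "biomass": "cn",
    "autotroph": "biomass & p",
    "heterotroph": "biomass & ~p",
    "background": "~(cn | o)",
    "phosphate_high": "p & ~biomass",
}

#: Channels the log-threshold step is designed for.
SEGMENTATION_CHANNELS = ("16O", "12C14N", "31P")


@dataclass
class ThresholdResult:
    mask: np.ndarray
    threshold: float          # threshold on the log1p scale
    method: str
    channel: str = ""


@dataclass
class MaskSet:
    """Background / autotroph / heterotroph / phosphate-high binary masks."""

    background: np.ndarray
    autotroph: np.ndarray
    heterotroph: np.ndarray
    phosphate_high: np.ndarray
    recipe: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {m.shape for m in (self.background, self.autotroph,
                                    self.heterotroph, self.phosphate_high)}
        if len(shapes) != 1:
            raise ValidationError("mask shapes differ")

    def assert_partition(self) -> None:
        """Check the post-resolution partition invariants.

        Raw recipe output may leave the classes overlapping; after
        :func:`resolve_overlaps` the biomass classes must be disjoint and
        the background must not intersect either.
        """
        if np.any(self.autotroph & self.heterotroph):
            raise ValidationError("autotroph and heterotroph masks overlap")
        if np.any(self.background & (self.autotroph | self.heterotroph)):
            raise ValidationError("background overlaps a biomass class")


@dataclass
class CellRecord:
    """One segmented cell (an 8-connected component of one class)."""

    cell_id: int
    cell_class: str                 # "autotroph" | "heterotroph"
    pixel_indices: list             # [(row, col), ...]
    summed_counts: dict             # channel name -> int
    delta13C_cell: float            # permil, ratio of summed counts
    delta15N_cell: float
    pixel_deltas13C: list
    pixel_deltas15N: list
    excluded: bool = False          # True when no valid denominator counts

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_indices)


def log_threshold(channel_image, method: str = "otsu",
                  manual_value: float | None = None,
                  channel: str = "") -> ThresholdResult:
    """Threshold the log of a raw count image into high/low signal.

    ``log1p`` is used instead of ``log`` so zero-count pixels are admitted.
    ``manual_value`` is interpreted on the log1p scale.
    """
    img = np.log1p(np.asarray(channel_image, dtype=np.float64))
    if method == "manual":
        if manual_value is None:
            raise ValidationError("manual thresholding requires manual_value")
        thr = float(manual_value)
    elif method == "otsu":
        if img.max() == img.min():
            raise ThresholdError(
                "constant image: Otsu threshold is degenerate; "
                "use method='manual' with an explicit value"
            )
        thr = float(threshold_otsu(img))
    else:
        raise ValidationError(f"unknown threshold method '{method}'")
    return ThresholdResult(mask=img > thr, threshold=thr, method=method,
                           channel=channel)


def _eval_recipe_expr(expr: str, names: dict) -> np.ndarray:
    allowed = set(names)
    code = compile(expr, "<recipe>", "eval")
    for name in code.co_names:
        if name not in allowed:
            raise ConfigError(
                f"recipe refers to unknown input '{name}' "
                f"(allowed: {sorted(allowed)})"
            )
    return np.asarray(eval(code, {"__builtins__": {}}, names), dtype=bool)


def build_masks(o_mask, cn_mask, p_mask, recipe: dict | None = None) -> MaskSet:
    """Combine the three thresholded channel masks into class masks."""
    o = np.asarray(o_mask, dtype=bool)
    cn = np.asarray(cn_mask, dtype=bool)
    p = np.asarray(p_mask, dtype=bool)
    if not (o.shape == cn.shape == p.shape):
        raise ValidationError("input masks must share one shape")
    recipe = dict(DEFAULT_RECIPE if recipe is None else recipe)
    names = {"o": o, "cn": cn, "p": p}
    if "biomass" in recipe:
        names["biomass"] = _eval_recipe_expr(recipe["biomass"], names)
    out = {}
    for key in ("autotroph", "heterotroph", "background", "phosphate_high"):
        if key not in recipe:
            raise ConfigError(f"recipe missing expression for '{key}'")
        out[key] = _eval_recipe_expr(recipe[key], names)
    return MaskSet(
        background=out["background"],
        autotroph=out["autotroph"],
        heterotroph=out["heterotroph"],
        phosphate_high=out["phosphate_high"],
        recipe=recipe,
    )


def cleanup(mask, min_object_px: int = 5, opening_radius: int = 1) -> np.ndarray:
    """Binary opening followed by small-object removal (8-connectivity).

    The opening footprint is the chessboard ball of the stated radius (a
    (2r+1)-square), matching the package-wide 8-connectivity convention.
    Components with fewer than ``min_object_px`` pixels are removed.
    Idempotent for fixed parameters.
    """
    if min_object_px < 0:
        raise ValidationError("min_object_px must be >= 0")
    m = np.asarray(mask, dtype=bool)
    if opening_radius > 0:
        side = 2 * opening_radius + 1
        m = opening(m, footprint_rectangle((side, side))).astype(bool)
    if min_object_px > 1:
        # max_size removes components of size <= value, i.e. size < min_object_px
        m = remove_small_objects(m, connectivity=2, max_size=min_object_px - 1)
    return m


_EIGHT = np.ones((3, 3), dtype=bool)


def resolve_overlaps(masks: MaskSet, overlap_fraction_cutoff: float = 0.5) -> MaskSet:
    """Apply the on-top vs side-attached heterotroph exclusion rule.

    Each 8-connected heterotroph component overlapping the autotroph mask by
    more than ``overlap_fraction_cutoff`` of its own area is deleted (cells
    lying on top of a filament are not analyzable); components at or below
    the cutoff are kept, with their overlapping pixels reassigned to the
    autotroph class.  Merely touching components are kept intact.
    """
    het = masks.heterotroph.copy()
    auto = masks.autotroph.copy()
    labels, n = ndi.label(het, structure=_EIGHT)
    for comp_id in range(1, n + 1):
        comp = labels == comp_id
        overlap = comp & auto
        frac = overlap.sum() / comp.sum()
        if frac > overlap_fraction_cutoff:
            het[comp] = False
        else:
            het[overlap] = False  # those pixels stay autotroph
    return MaskSet(
        background=masks.background & ~(auto | het),
        autotroph=auto,
        heterotroph=het,
        phosphate_high=masks.phosphate_high,
        recipe={**masks.recipe,
                "overlap_fraction_cutoff": overlap_fraction_cutoff},
    )


def label_cells(masks: MaskSet, enrich: EnrichmentMaps,
                summed: SummedImage) -> list[CellRecord]:
    """Extract per-cell records from the class masks.

    Cells are 8-connected components.  Pixels in the phosphate-high region
    are excluded from every record; per-cell deltas are computed from the
    counts summed over the cell's valid pixels (ratio of sums).  A cell
    whose valid pixels carry no denominator counts is flagged ``excluded``.
    """
    if masks.autotroph.shape != enrich.delta13C.shape:
        raise ValidationError("masks and enrichment maps must share shape")
    refs = enrich.references
    records: list[CellRecord] = []
    next_id = 1
    for cls, cls_mask in (("autotroph", masks.autotroph),
                          ("heterotroph", masks.heterotroph)):
        usable = cls_mask & ~masks.phosphate_high
        labels, n = ndi.label(usable, structure=_EIGHT)
        for comp_id in range(1, n + 1):
            comp = labels == comp_id
            rows, cols = np.nonzero(comp)
            counts = {name: int(summed.channel(name)[comp].sum())
                      for name in summed.channel_names}
            v13 = comp & enrich.valid13
            v15 = comp & enrich.valid15
            c12 = int(summed.channel("12C12C")[v13].sum())
            c13 = int(summed.channel("12C13C")[v13].sum())
            n14 = int(summed.channel("12C14N")[v15].sum())
            n15 = int(summed.channel("12C15N")[v15].sum())
            excluded = c12 == 0 or n14 == 0
            d13 = (np.nan if c12 == 0 else
                   (c13 / c12 / 2.0 / refs.R_standard_13C - 1.0) * 1000.0)
            d15 = (np.nan if n14 == 0 else
                   (n15 / n14 / refs.R_standard_15N - 1.0) * 1000.0)
            records.append(CellRecord(
                cell_id=next_id,
                cell_class=cls,
                pixel_indices=list(zip(rows.tolist(), cols.tolist())),
                summed_counts=counts,
                delta13C_cell=d13,
                delta15N_cell=d15,
                pixel_deltas13C=enrich.delta13C[v13].tolist(),
                pixel_deltas15N=enrich.delta15N[v15].tolist(),
                excluded=excluded,
            ))
            next_id += 1
    return records


def jaccard(a, b) -> float:
    """Jaccard overlap |a & b| / |a | b| between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def segment_stack(summed: SummedImage, recipe: dict | None = None,
                  min_object_px: int = 5, opening_radius: int = 1,
                  overlap_fraction_cutoff: float = 0.5,
                  thresholds: dict | None = None) -> tuple[MaskSet, dict]:
    """Full segmentation of a summed image; returns masks and provenance.

    ``thresholds`` maps channel name -> manual log1p threshold; channels
    not listed use the automatic Otsu threshold.
    """
    thresholds = thresholds or {}
    results = {}
    for name in SEGMENTATION_CHANNELS:
        if name in thresholds:
            results[name] = log_threshold(summed.channel(name), "manual",
                                          thresholds[name], channel=name)
        else:
            results[name] = log_threshold(summed.channel(name), "otsu",
                                          channel=name)
    masks = build_masks(results["16O"].mask, results["12C14N"].mask,
                        results["31P"].mask, recipe=recipe)
    auto = cleanup(masks.autotroph, min_object_px, opening_radius)
    het = cleanup(masks.heterotroph, min_object_px, opening_radius)
    masks = MaskSet(
        background=masks.background & ~(auto | het),
        autotroph=auto,
        heterotroph=het & ~auto,
        phosphate_high=masks.phosphate_high,
        recipe=masks.recipe,
    )
    masks = resolve_overlaps(masks, overlap_fraction_cutoff)
    masks.assert_partition()
    provenance = {
        "thresholds_log1p": {n: results[n].threshold
                             for n in SEGMENTATION_CHANNELS},
        "threshold_methods": {n: results[n].method
                              for n in SEGMENTATION_CHANNELS},
        "recipe": masks.recipe,
        "min_object_px": min_object_px,
        "opening_radius": opening_radius,
        "overlap_fraction_cutoff": overlap_fraction_cutoff,
    }
    return masks, provenance
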