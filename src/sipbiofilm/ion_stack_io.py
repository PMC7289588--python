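"""Containers and I/O for multi-channel NanoSIMS ion-count image stacks.

A stack holds raw secondary-ion counts indexed ``(plane, channel, row, col)``
for the six simultaneously detected species (16O-, 12C12C-, 12C13C-,
12C14N-, 12C15N-, 31P-).  This module is the single place where file
dialects are decided: the native interchange format is a multi-page TIFF
with the acquisition metadata stored as JSON in the shaped-metadata tag, and
a compressed NumPy archive is supported as an alternative.  The vendor
proprietary ``.im`` format is explicitly unsupported.

Coordinate convention (inherited by every other module): 0-based, row-major,
row = image y increasing downward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import FormatError, ValidationError

#: Canonical channel order used throughout the package.
CHANNELS = ("16O", "12C12C", "12C13C", "12C14N", "12C15N", "31P")


@dataclass
class IonImageStack:
    """Multi-plane, multi-channel integer ion-count image stack.

    Parameters
    ----------
    counts
        Non-negative integer array of shape ``(n_planes, n_channels,
        height, width)``; stored as unsigned 32-bit.
    channel_names
        Ordered channel names drawn from :data:`CHANNELS`, unique.
    pixel_size_um
        Lateral pixel size in micrometres.
    dwell_time_ms_per_px
        Primary-beam dwell time per pixel, in milliseconds.
    acquisition_tag
        Free-text provenance string.
    """

    counts: np.ndarray
    channel_names: tuple = CHANNELS
    pixel_size_um: float = 40.0 / 256.0
    dwell_time_ms_per_px: float = 2.0
    acquisition_tag: str = ""

    def __post_init__(self):
        self.channel_names = tuple(self.channel_names)
        counts = np.asarray(self.counts)
        if counts.ndim != 4:
            raise ValidationError(
                f"counts must be (plane, channel, row, col); got ndim={counts.ndim}"
            )
        if np.issubdtype(counts.dtype, np.floating):
            if not np.all(counts == np.floor(counts)):
                raise ValidationError("counts must be integers")
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        unknown = set(self.channel_names) - set(CHANNELS)
        if unknown:
            raise FormatError(f"unknown channel name(s): {sorted(unknown)}")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise FormatError("channel names must be unique")
        if counts.shape[1] != len(self.channel_names):
            raise ValidationError(
                f"{counts.shape[1]} channel planes but "
                f"{len(self.channel_names)} channel names"
            )
        if self.pixel_size_um <= 0 or self.dwell_time_ms_per_px <= 0:
            raise ValidationError("pixel size and dwell time must be positive")
        self.counts = counts.astype(np.uint32)

    @property
    def n_planes(self) -> int:
        return self.counts.shape[0]

    @property
    def shape(self) -> tuple:
        """(height, width) of a single plane."""
        return self.counts.shape[2:]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise FormatError(f"stack has no channel named '{name}'") from None


@dataclass
class SummedImage:
    """Plane-summed ion counts, indexed ``(channel, row, col)``."""

    counts: np.ndarray
    channel_names: tuple = CHANNELS
    provenance: str = ""

    def __post_init__(self):
        self.channel_names = tuple(self.channel_names)
        self.counts = np.asarray(self.counts, dtype=np.int64)

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise FormatError(f"summed image has no channel named '{name}'") from None
        return self.counts[idx]


def sum_planes(stack: IonImageStack, plane_range=None) -> SummedImage:
    """Sum a stack over planes (default: all planes).

    ``plane_range`` is a half-open ``(start, stop)`` pair in plane indices.
    """
    if plane_range is None:
        start, stop = 0, stack.n_planes
    else:
        start, stop = plane_range
    if not (0 <= start < stop <= stack.n_planes):
        raise ValidationError(
            f"empty or out-of-bounds plane range ({start}, {stop}) "
            f"for {stack.n_planes} planes"
        )
    summed = stack.counts[start:stop].astype(np.int64).sum(axis=0)
    return SummedImage(
        counts=summed,
        channel_names=stack.channel_names,
        provenance=f"{stack.acquisition_tag or 'stack'}:planes[{start}:{stop}]",
    )


# ---------------------------------------------------------------------------
# TIFF dialect

def write_stack(stack: IonImageStack, path) -> None:
    """Write a stack as a multi-page TIFF with JSON metadata."""
    meta = {
        "channel_names": list(stack.channel_names),
        "pixel_size_um": stack.pixel_size_um,
        "dwell_time_ms_per_px": stack.dwell_time_ms_per_px,
        "acquisition_tag": stack.acquisition_tag,
    }
    tifffile.imwrite(path, stack.counts, photometric="minisblack", metadata=meta)


def read_stack(path) -> IonImageStack:
    """Read a stack written by :func:`write_stack` (bit-exact round trip)."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.series[0].asarray()
        shaped = tf.shaped_metadata
        if not shaped:
            raise FormatError(f"{path}: no channel metadata present")
        meta = dict(shaped[0])
    for key in ("channel_names", "pixel_size_um", "dwell_time_ms_per_px"):
        if key not in meta:
            raise FormatError(f"{path}: metadata missing '{key}'")
    if arr.ndim == 3:  # single plane stored without the plane axis
        arr = arr[None]
    names = tuple(meta["channel_names"])
    missing = set(CHANNELS) - set(names)
    if missing:
        raise FormatError(f"{path}: missing channel(s) {sorted(missing)}")
    return IonImageStack(
        counts=arr,
        channel_names=names,
        pixel_size_um=float(meta["pixel_size_um"]),
        dwell_time_ms_per_px=float(meta["dwell_time_ms_per_px"]),
        acquisition_tag=str(meta.get("acquisition_tag", "")),
    )


# ---------------------------------------------------------------------------
# Compressed array archive

def write_stack_npz(stack: IonImageStack, path) -> None:
    np.savez_compressed(
        path,
        counts=stack.counts,
        channel_names=np.array(stack.channel_names),
        pixel_size_um=stack.pixel_size_um,
        dwell_time_ms_per_px=stack.dwell_time_ms_per_px,
        acquisition_tag=stack.acquisition_tag,
    )


def read_stack_npz(path) -> IonImageStack:
    with np.load(path, allow_pickle=False) as z:
        return IonImageStack(
            counts=z["counts"],
            channel_names=tuple(str(n) for n in z["channel_names"]),
            pixel_size_um=float(z["pixel_size_um"]),
            dwell_time_ms_per_px=float(z["dwell_time_ms_per_px"]),
            acquisition_tag=str(z["acquisition_tag"]),
        )


def write_label_image(labels: np.ndarray, path, meta: dict | None = None) -> None:
    """Write an integer label map (e.g. class or cell-id map) as TIFF."""
    tifffile.imwrite(
        path,
        np.asarray(labels).astype(np.int32),
        photometric="minisblack",
        metadata=meta or {},
    )


def read_label_image(path) -> np.ndarray:
    return tifffile.imread(path)
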