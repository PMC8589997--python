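"""On-disk container for FLIM decay stacks, label masks and study tables.

A decay stack is stored as one multi-page 16-bit TIFF per detection channel
(one page per temporal bin) plus a single JSON sidecar holding the
acquisition metadata.  The format is deliberately plain: bit-exact,
inspectable with any TIFF reader, and round-trips losslessly.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, Field, field_validator

logger = logging.getLogger(__name__)

DEFAULT_LASER_PERIOD_NS = 12.48
DEFAULT_N_BINS = 24


class Channel(str, Enum):
    NADPH = "NADPH"
    FAD = "FAD"


class Condition(str, Enum):
    control = "control"
    uva1_25 = "uva1_25"
    uva1_40 = "uva1_40"
    uva1_40_sunscreen = "uva1_40_sunscreen"


class Timepoint(str, Enum):
    T0 = "T0"
    T30min = "T30min"
    T2h = "T2h"


class Layer(str, Enum):
    basal = "basal"
    dermis = "dermis"


#: UVA1 dose in J/cm^2 implied by each exposure condition.
DOSE_BY_CONDITION = {
    Condition.control: 0,
    Condition.uva1_25: 25,
    Condition.uva1_40: 40,
    Condition.uva1_40_sunscreen: 40,
}


class StackFormatError(ValueError):
    """Raised when an on-disk stack does not match its declared metadata."""


class AcquisitionMeta(BaseModel):
    """Per-channel acquisition metadata of a TCSPC decay stack.

    ``bin_width`` is always derived from ``laser_period / n_bins`` and never
    stored independently, so the two cannot drift apart.
    """

    laser_period: float = Field(default=DEFAULT_LASER_PERIOD_NS, gt=0.0)
    n_bins: int = Field(default=DEFAULT_N_BINS, ge=2)
    channel: Channel = Channel.NADPH
    condition: Condition | None = None
    timepoint: Timepoint | None = None
    layer: Layer | None = None
    sample_id: str = ""
    roi_id: str = ""
    pixel_size: float = Field(default=0.5, gt=0.0)  # µm / px

    model_config = {"frozen": True}

    @field_validator("laser_period")
    @classmethod
    def _finite_period(cls, v: float) -> float:
        if not np.isfinite(v):
            raise ValueError("laser_period must be finite")
        return v

    @property
    def bin_width(self) -> float:
        """Temporal bin width in ns (laser_period / n_bins, derived)."""
        return self.laser_period / self.n_bins

    @property
    def omega(self) -> float:
        """First-harmonic angular frequency 2*pi/laser_period in rad/ns."""
        return 2.0 * np.pi / self.laser_period

    @property
    def bin_midpoints(self) -> np.ndarray:
        """Midpoint time of each temporal bin, ns."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass
class DecayStack:
    """Per-channel X x Y x T photon-count histograms with metadata.

    ``counts`` maps channel name to an (X, Y, T) array.  Counts are
    non-negative; integer dtype for measured data, float64 for the exact
    noise-free stacks produced by the simulator (those cannot be written to
    disk unless integer-valued).
    """

    counts: dict[str, np.ndarray]
    meta: dict[str, AcquisitionMeta]
    _skip_validation: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if self._skip_validation:
            return
        if not self.counts:
            raise ValueError("DecayStack needs at least one channel")
        if set(self.counts) != set(self.meta):
            raise ValueError("counts and meta must list the same channels")
        shapes = {c: a.shape for c, a in self.counts.items()}
        xy = {s[:2] for s in shapes.values()}
        if len(xy) != 1:
            raise ValueError(f"channels must share X, Y dimensions, got {shapes}")
        for chan, arr in self.counts.items():
            if arr.ndim != 3:
                raise ValueError(f"channel {chan!r}: counts must be 3-D (X, Y, T)")
            if arr.shape[2] != self.meta[chan].n_bins:
                raise StackFormatError(
                    f"channel {chan!r}: {arr.shape[2]} temporal bins on array, "
                    f"metadata declares n_bins={self.meta[chan].n_bins}"
                )
            if arr.size and arr.min() < 0:
                raise ValueError(f"channel {chan!r}: negative photon counts")

    @property
    def channels(self) -> list[str]:
        return list(self.counts)

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.counts.values()))
        return first.shape[:2]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DecayStack):
            return NotImplemented
        return (
            set(self.counts) == set(other.counts)
            and all(np.array_equal(self.counts[c], other.counts[c]) for c in self.counts)
            and self.meta == other.meta
        )


def write_stack(stack: DecayStack, path: str | Path) -> Path:
    """Write a decay stack to ``path`` (a directory that is created).

    One multi-page uint16 TIFF per channel (one page per temporal bin, pages
    are (X, Y)) plus ``meta.json``.  Counts above the 16-bit range or
    non-integer-valued counts are refused rather than clipped.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for chan, arr in stack.counts.items():
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError(
                    f"channel {chan!r}: non-integer counts cannot be stored in "
                    "the uint16 container (noise-free float stacks are "
                    "in-memory objects)"
                )
        if arr.size and arr.max() > np.iinfo(np.uint16).max:
            raise OverflowError(
                f"channel {chan!r}: max count {int(arr.max())} exceeds the "
                f"16-bit container limit {np.iinfo(np.uint16).max}"
            )
        pages = np.ascontiguousarray(np.moveaxis(arr.astype(np.uint16), 2, 0))
        tifffile.imwrite(path / f"{chan}.tif", pages)
    meta_doc = {
        "format": "phasorflim-stack-v1",
        "channels": {c: stack.meta[c].model_dump(mode="json") for c in stack.counts},
    }
    (path / "meta.json").write_text(json.dumps(meta_doc, indent=1))
    return path


def read_stack(path: str | Path) -> Path | DecayStack:
    """Read a decay stack written by :func:`write_stack`.

    A missing ``laser_period`` in the sidecar is defaulted to 12.48 ns with a
    logged warning; a page count that disagrees with ``n_bins`` raises
    :class:`StackFormatError`.
    """
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"no meta.json under {path}")
    doc = json.loads(meta_file.read_text())
    counts: dict[str, np.ndarray] = {}
    meta: dict[str, AcquisitionMeta] = {}
    for chan, meta_dict in doc["channels"].items():
        meta_dict = dict(meta_dict)
        if meta_dict.get("laser_period") is None:
            meta_dict["laser_period"] = DEFAULT_LASER_PERIOD_NS
            logger.warning(
                "channel %s: laser_period missing from sidecar, "
                "defaulting to %.2f ns", chan, DEFAULT_LASER_PERIOD_NS,
            )
        m = AcquisitionMeta(**meta_dict)
        pages = tifffile.imread(path / f"{chan}.tif")
        if pages.ndim == 2:  # single page collapses
            pages = pages[None]
        if pages.shape[0] != m.n_bins:
            raise StackFormatError(
                f"channel {chan!r}: TIFF has {pages.shape[0]} pages, "
                f"metadata declares n_bins={m.n_bins}"
            )
        counts[chan] = np.moveaxis(pages, 0, 2)
        meta[chan] = m
    return DecayStack(counts=counts, meta=meta)


def write_mask(labels: np.ndarray, path: str | Path) -> Path:
    """Write an integer label mask as a single-page uint16 TIFF."""
    path = Path(path)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise OverflowError("label values outside the uint16 range")
    tifffile.imwrite(path, labels.astype(np.uint16))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


#: Stable column order of the tidy per-ROI / per-cell study table.
STUDY_COLUMNS = [
    "sample_id", "condition", "dose", "timepoint", "layer",
    "unit_type", "unit_id", "roi_id", "biomarker",
    "f_bound", "tau_phi", "tau_mod", "n_pixels",
]


def write_table(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a study table as CSV with the documented stable column order."""
    if len(records) == 0:
        raise ValueError("refusing to write an empty study table")
    cols = [c for c in STUDY_COLUMNS if c in records.columns]
    cols += [c for c in records.columns if c not in cols]
    path = Path(path)
    records[cols].to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
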