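"""Measurement containers, ROI extraction and the tidy dataset CSV.

The unit of observation is one photograph of one oil blend: the mean RGB of
a region of interest (ROI) placed over the oil, plus the mean RGB of a
second ROI over the empty part of the test tube directly above the sample
(the "blank", which witnesses the scene's lighting).  A tidy CSV with one
row per observation is the interchange format every downstream stage
consumes.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import (
    DatasetValidationError,
    ImageFormatError,
    RoiBoundsError,
    SchemaError,
)

#: Required columns of the tidy dataset CSV, in canonical order.
DATASET_COLUMNS = (
    "sample_id",
    "fraction",
    "condition",
    "r_sample",
    "g_sample",
    "b_sample",
    "r_blank",
    "g_blank",
    "b_blank",
)

_RGB_COLUMNS = DATASET_COLUMNS[3:]


def as_rgb(values) -> np.ndarray:
    """Coerce a length-3 sequence to a float64 RGB triplet array."""
    rgb = np.asarray(values, dtype=float)
    if rgb.shape != (3,):
        raise ValueError(f"an RGB triplet must have exactly 3 values, got shape {rgb.shape}")
    return rgb


@dataclasses.dataclass(frozen=True)
class ROISpec:
    """A rectangular pixel window, 0-based and half-open.

    The window covers columns ``[x, x + width)`` and rows ``[y, y + height)``.
    The default 30 x 30 extent matches the patch size used for smartphone
    tube photographs.
    """

    x: int
    y: int
    width: int = 30
    height: int = 30

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI width and height must be >= 1")
        if self.x < 0 or self.y < 0:
            raise ValueError("ROI origin must be non-negative")


@dataclasses.dataclass(frozen=True)
class BlendSample:
    """One observation: blend fraction plus oil-ROI and blank-ROI mean RGB.

    ``fraction`` is the w/w proportion of the first mixture oil (the
    predicted quantity).  Channel values live on the 0-255 capture scale but
    are stored as floats; values rendered without 8-bit clipping may exceed
    255 slightly.
    """

    sample_id: str
    fraction: float
    condition: str
    sample_rgb: np.ndarray
    blank_rgb: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample_rgb", as_rgb(self.sample_rgb))
        object.__setattr__(self, "blank_rgb", as_rgb(self.blank_rgb))
        if not 0.0 <= self.fraction <= 1.0:
            raise DatasetValidationError(
                f"sample {self.sample_id!r}: fraction {self.fraction} outside [0, 1]"
            )


class BlendDataset:
    """An ordered collection of :class:`BlendSample` rows plus metadata.

    Backed by a :class:`pandas.DataFrame` with the :data:`DATASET_COLUMNS`
    schema.  ``metadata`` carries provenance (mixture name, condition tag,
    generator seed) and is not persisted in the CSV.
    """

    def __init__(self, frame: pd.DataFrame, metadata: dict | None = None):
        missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"dataset is missing column(s): {', '.join(missing)}")
        frame = frame.loc[:, list(DATASET_COLUMNS)].reset_index(drop=True)
        frame = frame.astype({c: float for c in ("fraction",) + _RGB_COLUMNS})
        bad = frame.index[(frame["fraction"] < 0) | (frame["fraction"] > 1)]
        if len(bad):
            raise DatasetValidationError(
                f"fraction outside [0, 1] in row(s): {', '.join(str(i) for i in bad)}"
            )
        self.frame = frame
        self.metadata = dict(metadata or {})

    # -- construction -----------------------------------------------------
    @classmethod
    def from_samples(
        cls, samples: Iterable[BlendSample], metadata: dict | None = None
    ) -> "BlendDataset":
        rows = []
        for s in samples:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "fraction": s.fraction,
                    "condition": s.condition,
                    "r_sample": s.sample_rgb[0],
                    "g_sample": s.sample_rgb[1],
                    "b_sample": s.sample_rgb[2],
                    "r_blank": s.blank_rgb[0],
                    "g_blank": s.blank_rgb[1],
                    "b_blank": s.blank_rgb[2],
                }
            )
        return cls(pd.DataFrame(rows, columns=list(DATASET_COLUMNS)), metadata)

    # -- access -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def fractions(self) -> np.ndarray:
        return self.frame["fraction"].to_numpy()

    @property
    def sample_rgb(self) -> np.ndarray:
        """(n, 3) array of oil-ROI mean RGB."""
        return self.frame[["r_sample", "g_sample", "b_sample"]].to_numpy()

    @property
    def blank_rgb(self) -> np.ndarray:
        """(n, 3) array of blank-ROI mean RGB."""
        return self.frame[["r_blank", "g_blank", "b_blank"]].to_numpy()

    @property
    def condition(self) -> str | None:
        tags = self.frame["condition"].unique()
        return str(tags[0]) if len(tags) == 1 else None

    def iter_samples(self) -> Iterator[BlendSample]:
        for row in self.frame.itertuples(index=False):
            yield BlendSample(
                sample_id=str(row.sample_id),
                fraction=float(row.fraction),
                condition=str(row.condition),
                sample_rgb=np.array([row.r_sample, row.g_sample, row.b_sample]),
                blank_rgb=np.array([row.r_blank, row.g_blank, row.b_blank]),
            )

    def subset(self, indices, metadata: dict | None = None) -> "BlendDataset":
        """Row subset in the given index order; metadata is carried over."""
        meta = dict(self.metadata)
        meta.update(metadata or {})
        return BlendDataset(self.frame.iloc[np.asarray(indices)], meta)

    def equals(self, other: "BlendDataset", tol: float = 1e-6) -> bool:
        """Equality of rows up to ``tol`` on numeric columns (order matters)."""
        if len(self) != len(other):
            return False
        a, b = self.frame, other.frame
        if not (a["sample_id"].tolist() == b["sample_id"].tolist()):
            return False
        if not (a["condition"].tolist() == b["condition"].tolist()):
            return False
        num = ["fraction", *(_RGB_COLUMNS)]
        return bool(np.allclose(a[num].to_numpy(), b[num].to_numpy(), atol=tol))


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_roi_mean(image: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Mean of the first three channels over a rectangular ROI.

    Parameters
    ----------
    image
        ``(H, W, C)`` array with ``C >= 3``; any extra channels (e.g. alpha)
        are ignored.  Integer images are averaged on the 0-255 scale.
    roi
        Half-open pixel window; must lie fully inside the image.

    Returns
    -------
    Length-3 float array: per-channel arithmetic mean.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ImageFormatError(
            f"expected an image with >= 3 channels, got shape {image.shape}"
        )
    h, w = image.shape[:2]
    if roi.x + roi.width > w or roi.y + roi.height > h:
        raise RoiBoundsError(
            f"ROI {roi} exceeds image bounds ({w} x {h} pixels)"
        )
    patch = image[roi.y : roi.y + roi.height, roi.x : roi.x + roi.width, :3]
    return patch.astype(float).mean(axis=(0, 1))


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF raster into an ``(H, W, C)`` array."""
    return iio.imread(Path(path))


# ---------------------------------------------------------------------------
# Tidy CSV round-trip
# ---------------------------------------------------------------------------

def read_dataset(path: str | Path, metadata: dict | None = None) -> BlendDataset:
    """Read a tidy measurement CSV into a :class:`BlendDataset`.

    Malformed numeric fields and out-of-range fractions are reported with
    1-based file line numbers (header is line 1).
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"sample_id": str, "condition": str})
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    numeric = ["fraction", *(_RGB_COLUMNS)]
    coerced = frame[numeric].apply(pd.to_numeric, errors="coerce")
    bad_rows = coerced.index[coerced.isna().any(axis=1)]
    if len(bad_rows):
        lines = ", ".join(str(i + 2) for i in bad_rows)
        raise DatasetValidationError(
            f"{path.name}: non-numeric measurement value(s) on line(s) {lines}"
        )
    frame[numeric] = coerced
    out_of_range = frame.index[(frame["fraction"] < 0) | (frame["fraction"] > 1)]
    if len(out_of_range):
        lines = ", ".join(str(i + 2) for i in out_of_range)
        raise DatasetValidationError(
            f"{path.name}: fraction outside [0, 1] on line(s) {lines}"
        )
    return BlendDataset(frame, metadata)


def write_dataset(dataset: BlendDataset, path: str | Path) -> None:
    """Write the tidy CSV (UTF-8, '.' decimal separator, row order kept)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dataset.frame.to_csv(path, index=False)
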