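"""Lighting corrections and descriptor-subset selection.

Three corrections turn raw sample RGB into lighting-robust descriptors,
each using the blank (the empty-tube patch above the oil) as a witness of
the shot's illumination:

* **illuminance** — divide every sample channel by the blank's theoretical
  illuminance Y, a fixed linear combination of the blank RGB approximating
  the CIE Y tristimulus component.  Invariant to a common positive scaling
  of sample and blank, i.e. to the per-shot lightness effect.
* **blanks difference** — subtract from each sample channel the deviation
  of its own blank from the mean blank of the primary calibration series.
  Invariant to additive offsets shared by sample and blank.
* **blanks ratio** — multiply each sample channel by (primary mean blank /
  own blank).  Invariant to per-channel gains shared by sample and blank.

Corrected values are model inputs, not displayable colors, and are never
clipped back to [0, 255].
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
import pandas as pd

from .dataio import BlendDataset, BlendSample, as_rgb
from .errors import DegenerateBlankError

#: Weights of the theoretical-illuminance approximation Y = w . RGB.
ILLUMINANCE_WEIGHTS = np.array([-0.32466, 1.57837, -0.73191])

#: Guard for divisions by illuminance or blank channels.
DEFAULT_EPSILON = 1e-6


class CorrectionMethod(str, enum.Enum):
    """The closed set of lighting corrections."""

    NONE = "none"
    ILLUMINANCE = "illuminance"
    BLANKS_DIFFERENCE = "blanks_difference"
    BLANKS_RATIO = "blanks_ratio"

    @property
    def needs_primary_blank(self) -> bool:
        return self in (CorrectionMethod.BLANKS_DIFFERENCE, CorrectionMethod.BLANKS_RATIO)


class DescriptorSet(str, enum.Enum):
    """Channel subset used as regression descriptors."""

    RGB = "RGB"
    RG = "RG"
    RB = "RB"
    GB = "GB"

    @property
    def indices(self) -> tuple[int, ...]:
        return {"RGB": (0, 1, 2), "RG": (0, 1), "RB": (0, 2), "GB": (1, 2)}[self.value]

    def __len__(self) -> int:
        return len(self.indices)


@dataclasses.dataclass(frozen=True)
class PrimaryBlankMean:
    """Per-channel mean blank of the primary calibration series.

    Both white-reference corrections compare each shot's own blank against
    this stored primary mean; during calibration transfer it travels with
    the fitted model and is never recomputed from secondary data.
    """

    mean_rgb: np.ndarray
    n: int

    def __post_init__(self):
        object.__setattr__(self, "mean_rgb", as_rgb(self.mean_rgb))
        if self.n < 1:
            raise ValueError("PrimaryBlankMean requires n >= 1")


# ---------------------------------------------------------------------------
# Per-sample corrections
# ---------------------------------------------------------------------------

def illuminance_of_blank(blank_rgb) -> float:
    """Theoretical illuminance Y of a blank: -0.32466 R + 1.57837 G - 0.73191 B."""
    return float(ILLUMINANCE_WEIGHTS @ as_rgb(blank_rgb))


def correct_illuminance(sample: BlendSample, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Divide the sample RGB by its own blank's illuminance Y.

    A non-positive Y means the blank is not a plausible white reference
    (blue-dominant or dark patch) and raises :class:`DegenerateBlankError`.
    """
    y = illuminance_of_blank(sample.blank_rgb)
    if y <= epsilon:
        raise DegenerateBlankError(
            f"sample {sample.sample_id!r}: blank illuminance Y={y:.6g} is not positive; "
            "the blank ROI is not a plausible white reference",
            sample_id=sample.sample_id,
        )
    return sample.sample_rgb / y


def correct_blanks_difference(sample: BlendSample, primary: PrimaryBlankMean) -> np.ndarray:
    """Channel-wise ``sample - (own_blank - primary_mean_blank)``."""
    return sample.sample_rgb - (sample.blank_rgb - primary.mean_rgb)


def correct_blanks_ratio(
    sample: BlendSample, primary: PrimaryBlankMean, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """Channel-wise ``sample * (primary_mean_blank / own_blank)``."""
    if np.any(sample.blank_rgb <= epsilon):
        raise DegenerateBlankError(
            f"sample {sample.sample_id!r}: blank channel(s) {sample.blank_rgb} too close "
            "to zero for the blanks-ratio correction",
            sample_id=sample.sample_id,
        )
    return sample.sample_rgb * (primary.mean_rgb / sample.blank_rgb)


# ---------------------------------------------------------------------------
# Dataset-level operations
# ---------------------------------------------------------------------------

def primary_blank_mean(dataset: BlendDataset) -> PrimaryBlankMean:
    """Per-channel arithmetic mean over all blanks of the given dataset."""
    if len(dataset) == 0:
        raise ValueError("cannot compute a primary blank mean from an empty dataset")
    return PrimaryBlankMean(mean_rgb=dataset.blank_rgb.mean(axis=0), n=len(dataset))


def apply_correction(
    dataset: BlendDataset,
    method: CorrectionMethod | str,
    primary: PrimaryBlankMean | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """Corrected sample triplets for every row of a dataset.

    Returns an ``(n, 3)`` float array.  ``primary`` is required for the two
    white-reference methods; per-sample degenerate-blank failures propagate
    with the offending ``sample_id``.
    """
    method = CorrectionMethod(method)
    if method.needs_primary_blank and primary is None:
        raise ValueError(f"correction {method.value!r} requires a PrimaryBlankMean")
    if method is CorrectionMethod.NONE:
        return dataset.sample_rgb.copy()
    corrected = np.empty((len(dataset), 3), dtype=float)
    for i, sample in enumerate(dataset.iter_samples()):
        if method is CorrectionMethod.ILLUMINANCE:
            corrected[i] = correct_illuminance(sample, epsilon)
        elif method is CorrectionMethod.BLANKS_DIFFERENCE:
            corrected[i] = correct_blanks_difference(sample, primary)
        else:
            corrected[i] = correct_blanks_ratio(sample, primary, epsilon)
    return corrected


def select_descriptors(triplet, descriptor_set: DescriptorSet | str) -> np.ndarray:
    """Project one corrected RGB triplet onto a descriptor subset."""
    descriptor_set = DescriptorSet(descriptor_set)
    return as_rgb(triplet)[list(descriptor_set.indices)]


def descriptor_matrix(corrected: np.ndarray, descriptor_set: DescriptorSet | str) -> np.ndarray:
    """Project ``(n, 3)`` corrected triplets onto the descriptor columns."""
    descriptor_set = DescriptorSet(descriptor_set)
    return np.asarray(corrected, dtype=float)[:, list(descriptor_set.indices)]


def corrected_frame(
    dataset: BlendDataset,
    method: CorrectionMethod | str,
    primary: PrimaryBlankMean | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """The dataset frame with ``r_corr``/``g_corr``/``b_corr`` columns appended."""
    corrected = apply_correction(dataset, method, primary, epsilon)
    frame = dataset.frame.copy()
    frame[["r_corr", "g_corr", "b_corr"]] = corrected
    return frame
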