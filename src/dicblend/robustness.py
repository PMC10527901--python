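"""Calibration transfer: score a primary-condition model on secondary data.

A model built under one acquisition condition (device x illumination) is
applied, unchanged, to measurement series captured under other conditions.
Each secondary sample is corrected with the model's own stored primary mean
blank (never a blank mean recomputed from secondary data — that would be
recalibration, not a transfer test), projected onto the model's descriptor
subset, and predicted; RMSE, R-squared and r2m against the true secondary
fractions quantify robustness.  r2m >= 0.5 is read as "congruent".
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (
    MLRModel,
    ValidationReport,
    evaluate_primary,
    predict,
    r2m,
    rmse_and_r2,
)
from .dataio import BlendDataset
from .preprocessing import (
    CorrectionMethod,
    DescriptorSet,
    apply_correction,
    descriptor_matrix,
)

#: r2m at or above this is reported as congruent observed/predicted agreement.
CONGRUENCE_THRESHOLD = 0.5

TRANSFER_COLUMNS = (
    "descriptor_set",
    "condition",
    "correction",
    "rmse",
    "r2",
    "r2m",
    "congruent",
)


@dataclasses.dataclass
class TransferReport:
    """Grid of transfer statistics, one row per (descriptors, condition, correction)."""

    table: pd.DataFrame
    primary_condition: str | None = None
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in TRANSFER_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"transfer table missing column(s): {missing}")


def evaluate_secondary(
    model: MLRModel,
    secondary: BlendDataset,
    correction: CorrectionMethod | str | None = None,
) -> dict:
    """Score a fitted primary model on one secondary-condition dataset.

    Returns ``{"rmse", "r2", "r2m"}``.  The correction defaults to the
    model's own; the two white-reference corrections use the primary mean
    blank stored in the model.  Passing data from the primary condition
    itself triggers a warning (self-transfer is a sanity check, not a
    robustness result).
    """
    correction = model.correction if correction is None else CorrectionMethod(correction)
    primary_tag = model.training_meta.get("condition")
    if primary_tag is not None and secondary.condition == primary_tag:
        warnings.warn(
            f"secondary dataset has the primary condition tag {primary_tag!r}; "
            "this is a self-transfer, not a robustness test",
            stacklevel=2,
        )
    corrected = apply_correction(secondary, correction, model.primary_blank)
    X = descriptor_matrix(corrected, model.descriptor_set)
    pred = predict(model, X)
    stats = rmse_and_r2(secondary.fractions, pred)
    stats["r2m"] = r2m(secondary.fractions, pred)
    return stats


def transfer_table(
    models: dict[tuple[str, str], MLRModel],
    secondary_datasets: list[BlendDataset],
) -> pd.DataFrame:
    """Assemble the transfer grid from prefit models.

    ``models`` maps ``(descriptor_set, correction)`` value pairs to fitted
    models; every model is scored on every secondary dataset.
    """
    rows = []
    for (dset, corr), model in models.items():
        for secondary in secondary_datasets:
            tag = secondary.metadata.get("condition", secondary.condition)
            try:
                stats = evaluate_secondary(model, secondary, corr)
            except Exception as err:
                raise type(err)(
                    f"transfer cell (descriptors={dset}, condition={tag}, "
                    f"correction={corr}): {err}"
                ) from err
            rows.append(
                {
                    "descriptor_set": dset,
                    "condition": tag,
                    "correction": corr,
                    "rmse": stats["rmse"],
                    "r2": stats["r2"],
                    "r2m": stats["r2m"],
                    "congruent": stats["r2m"] >= CONGRUENCE_THRESHOLD,
                }
            )
    return pd.DataFrame(rows, columns=list(TRANSFER_COLUMNS))


def run_condition_grid(
    primary_dataset: BlendDataset,
    secondary_datasets: list[BlendDataset],
    *,
    descriptor_sets=None,
    corrections=None,
    seed: int | None = None,
    n_perm: int = 100,
    cal_fraction: float = 0.8,
    scheme: str = "systematic",
    blank_scope: str = "all",
    models: dict | None = None,
) -> TransferReport:
    """Fit the descriptor x correction model grid on the primary condition
    and score every model on every secondary dataset.

    With the full default grids (4 descriptor sets x 4 corrections) and 3
    secondary conditions the report has 48 rows.  Prefit ``models`` (keyed
    ``(descriptor_value, correction_value)``) can be supplied to avoid
    refitting; otherwise each grid cell is fit via
    :func:`~dicblend.calibration.evaluate_primary` with the given seed.
    """
    if not secondary_datasets:
        raise ValueError("need at least one secondary dataset")
    descriptor_sets = [DescriptorSet(d) for d in (descriptor_sets or list(DescriptorSet))]
    corrections = [CorrectionMethod(c) for c in (corrections or list(CorrectionMethod))]
    if models is None:
        models = {}
        for dset in descriptor_sets:
            for corr in corrections:
                model, _ = evaluate_primary(
                    primary_dataset,
                    dset,
                    corr,
                    cal_fraction=cal_fraction,
                    scheme=scheme,
                    seed=seed,
                    n_perm=n_perm,
                    blank_scope=blank_scope,
                )
                models[(dset.value, corr.value)] = model
    table = transfer_table(models, secondary_datasets)
    return TransferReport(
        table=table,
        primary_condition=primary_dataset.metadata.get("condition"),
        metadata={
            "mixture": primary_dataset.metadata.get("mixture"),
            "seed": seed,
            "n_secondary": len(secondary_datasets),
        },
    )


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def validation_grid_frame(reports: dict[tuple[str, str], ValidationReport]) -> pd.DataFrame:
    """Long-form frame of a descriptor x correction validation grid.

    ``reports`` maps ``(descriptor_value, correction_value)`` to
    :class:`~dicblend.calibration.ValidationReport`; the output has one row
    per (descriptor_set, correction, stage, metric).
    """
    frames = []
    for (dset, corr), report in reports.items():
        frame = report.to_frame()
        frame.insert(0, "descriptor_set", dset)
        frame.insert(1, "correction", corr)
        frames.append(frame)
    columns = ["descriptor_set", "correction", "stage", "metric", "value"]
    if not frames:
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)[columns]


def _markdown_table(frame: pd.DataFrame) -> str:
    header = "| " + " | ".join(frame.columns) + " |"
    rule = "| " + " | ".join("---" for _ in frame.columns) + " |"
    lines = [header, rule]
    for row in frame.itertuples(index=False):
        cells = [f"{v:.4g}" if isinstance(v, float) else str(v) for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def render_report(reports, path: str | Path) -> None:
    """Write a report as CSV plus a Markdown table alongside.

    ``reports`` may be a :class:`TransferReport`, a mapping of
    ``(descriptor, correction)`` to validation reports, or an empty
    list/dict (which yields header-only files).  ``path`` names the CSV;
    the Markdown twin replaces its suffix with ``.md``.
    """
    if isinstance(reports, TransferReport):
        frame = reports.table
    elif isinstance(reports, dict):
        frame = validation_grid_frame(reports)
    elif not reports:
        frame = pd.DataFrame(columns=list(TRANSFER_COLUMNS))
    else:
        raise TypeError(f"cannot render reports of type {type(reports).__name__}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    path.with_suffix(".md").write_text(_markdown_table(frame))


def export_predictions(
    model: MLRModel, dataset: BlendDataset, path: str | Path
) -> pd.DataFrame:
    """Observed-vs-predicted plot data for one dataset under one model.

    Writes (and returns) a CSV with ``sample_id, condition, observed,
    predicted`` — the raw material of observed/predicted scatter figures.
    """
    corrected = apply_correction(dataset, model.correction, model.primary_blank)
    X = descriptor_matrix(corrected, model.descriptor_set)
    pred = predict(model, X)
    frame = pd.DataFrame(
        {
            "sample_id": dataset.frame["sample_id"],
            "condition": dataset.frame["condition"],
            "observed": dataset.fractions,
            "predicted": pred,
        }
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return frame
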