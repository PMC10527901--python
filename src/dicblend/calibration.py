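"""MLR calibration of blend fraction on color descriptors, with validation.

The calibration model is ordinary least squares of the blend fraction on a
subset of (possibly lighting-corrected) RGB channels.  The validation
battery mirrors standard chemometric practice for small calibration sets:

* calibration and external (hold-out) RMSE and R-squared,
* leave-one-out cross-validation,
* y-randomization (response permutation) with the cR2p summary
  ``sqrt(R2_cal) * sqrt(R2_cal - mean R2_rand)``, and
* the r2m congruence statistic, which penalises predictions that correlate
  with the observations but are not congruent with them (through-origin
  agreement).

Throughout, R-squared for observed-vs-predicted comparisons is the squared
Pearson correlation.  For the in-sample fit of an OLS model with intercept
this coincides with 1 - SSres/SStot; for hold-out and transfer predictions
it does not, and the correlation form is the one used here (it can remain
high under a pure bias, which is exactly what r2m then flags).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, LeaveOneOut

from .dataio import BlendDataset
from .errors import SingularDesignError
from .preprocessing import (
    CorrectionMethod,
    DescriptorSet,
    PrimaryBlankMean,
    apply_correction,
    descriptor_matrix,
    primary_blank_mean,
)

__all__ = [
    "MLRModel",
    "ValidationReport",
    "split_dataset",
    "fit_mlr",
    "predict",
    "rmse_and_r2",
    "r2m",
    "r2p",
    "y_randomization",
    "cross_validate",
    "evaluate_primary",
]


@dataclasses.dataclass
class MLRModel:
    """A fitted descriptor-subset MLR model.

    Carries everything needed to apply the model to new measurements: the
    descriptor subset, the lighting correction, and — for the two
    white-reference corrections — the stored mean blank of the primary
    calibration series.  ``descriptor_set`` may be ``None`` for bare
    numeric fits (e.g. single-column designs inside cross-validation).
    """

    descriptor_set: DescriptorSet | None
    correction: CorrectionMethod
    intercept: float
    coefficients: np.ndarray
    primary_blank: PrimaryBlankMean | None = None
    training_meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.descriptor_set is not None:
            self.descriptor_set = DescriptorSet(self.descriptor_set)
        self.correction = CorrectionMethod(self.correction)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.descriptor_set is not None and self.coefficients.shape != (
            len(self.descriptor_set),
        ):
            raise ValueError(
                f"{self.descriptor_set.value} model needs "
                f"{len(self.descriptor_set)} coefficients, got {self.coefficients.shape}"
            )

    # -- persistence ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "descriptor_set": (
                self.descriptor_set.value if self.descriptor_set is not None else None
            ),
            "correction": self.correction.value,
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "training_meta": self.training_meta,
        }
        if self.primary_blank is not None:
            d["primary_blank"] = {
                "mean_rgb": self.primary_blank.mean_rgb.tolist(),
                "n": self.primary_blank.n,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MLRModel":
        blank = d.get("primary_blank")
        return cls(
            descriptor_set=d["descriptor_set"],
            correction=d["correction"],
            intercept=float(d["intercept"]),
            coefficients=d["coefficients"],
            primary_blank=(
                PrimaryBlankMean(blank["mean_rgb"], int(blank["n"])) if blank else None
            ),
            training_meta=dict(d.get("training_meta", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "MLRModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclasses.dataclass
class ValidationReport:
    """The per-model statistics block of the validation battery.

    ``calibration`` and ``cross_validation`` hold ``{"rmse", "r2"}``;
    ``y_randomization`` holds ``{"rmse_mean", "r2_mean", "r2p"}``;
    ``external`` holds ``{"rmse", "r2", "r2m"}``.
    """

    calibration: dict
    cross_validation: dict
    y_randomization: dict
    external: dict

    def to_frame(self) -> pd.DataFrame:
        """Long-form (stage, metric, value) rows in report order."""
        rows = []
        for stage, metrics in (
            ("calibration", self.calibration),
            ("y_randomization", self.y_randomization),
            ("cross_validation", self.cross_validation),
            ("external", self.external),
        ):
            for metric, value in metrics.items():
                rows.append({"stage": stage, "metric": metric, "value": value})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_indices(
    fractions: np.ndarray,
    cal_fraction: float = 0.8,
    scheme: str = "systematic",
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (calibration, test) row indices.

    ``systematic`` sorts by fraction and holds out every m-th sample
    starting mid-period (m chosen from ``cal_fraction``), so the hold-out
    spans the concentration range and the 0 and 1 endpoints always stay in
    calibration; on the 41-level grid with ``cal_fraction=0.8`` this gives
    the 33/8 split.  ``random`` draws the hold-out uniformly with ``seed``.
    """
    fractions = np.asarray(fractions, dtype=float)
    n = len(fractions)
    if n < 5:
        raise ValueError(f"need at least 5 samples to split, got {n}")
    if not 0.0 < cal_fraction < 1.0:
        raise ValueError(f"cal_fraction must be in (0, 1), got {cal_fraction}")
    if scheme == "systematic":
        period = max(2, round(1.0 / (1.0 - cal_fraction)))
        order = np.argsort(fractions, kind="stable")
        positions = np.arange(n)
        is_test = positions % period == period // 2
        test = order[is_test]
        cal = order[~is_test]
        return np.sort(cal), np.sort(test)
    if scheme == "random":
        rng = np.random.default_rng(seed)
        n_test = max(1, round(n * (1.0 - cal_fraction)))
        perm = rng.permutation(n)
        return np.sort(perm[n_test:]), np.sort(perm[:n_test])
    raise ValueError(f"unknown split scheme {scheme!r}")


def split_dataset(
    dataset: BlendDataset,
    cal_fraction: float = 0.8,
    scheme: str = "systematic",
    seed: int | None = None,
) -> tuple[BlendDataset, BlendDataset]:
    """Split a dataset into (calibration, test) subsets; see :func:`split_indices`."""
    cal, test = split_indices(dataset.fractions, cal_fraction, scheme, seed)
    return (
        dataset.subset(cal, {"split": "calibration"}),
        dataset.subset(test, {"split": "test"}),
    )


# ---------------------------------------------------------------------------
# OLS core
# ---------------------------------------------------------------------------

def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def fit_mlr(
    X: np.ndarray,
    y: np.ndarray,
    descriptor_set: DescriptorSet | str | None = None,
    correction: CorrectionMethod | str = CorrectionMethod.NONE,
    primary_blank: PrimaryBlankMean | None = None,
    training_meta: dict | None = None,
) -> MLRModel:
    """Ordinary least squares with intercept.

    ``X`` is ``(n, p)`` descriptors, ``y`` the blend fractions; requires
    ``n >= p + 1`` (exact interpolation at the minimum) and a full-rank
    design.  ``descriptor_set`` may be
    omitted for bare numeric fits (permutation loops, oracle checks).
    """
    A = _design(X)
    y = np.asarray(y, dtype=float)
    n, p1 = A.shape
    if n < p1:
        raise ValueError(
            f"need at least p + 1 = {p1} samples for a unique fit, got {n}"
        )
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < p1:
        raise SingularDesignError(
            f"descriptor matrix is rank deficient (rank {rank} < {p1})"
        )
    return MLRModel(
        descriptor_set=None if descriptor_set is None else DescriptorSet(descriptor_set),
        correction=CorrectionMethod(correction),
        intercept=float(beta[0]),
        coefficients=beta[1:],
        primary_blank=primary_blank,
        training_meta=dict(training_meta or {}),
    )


def predict(model: MLRModel, X: np.ndarray) -> np.ndarray:
    """Predicted blend fractions: intercept + X @ coefficients, unclipped."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != len(model.coefficients):
        raise ValueError(
            f"descriptor arity mismatch: model has {len(model.coefficients)} "
            f"coefficients, X has {X.shape[1]} columns"
        )
    return model.intercept + X @ model.coefficients


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def rmse_and_r2(observed, predicted) -> dict:
    """Root-mean-squared error and squared Pearson correlation.

    Raises if ``observed`` is constant (the correlation is undefined); a
    constant ``predicted`` yields ``r2 = 0.0``.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if len(obs) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(obs) == 0:
        raise ValueError("R-squared is undefined for a constant observed vector")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.ptp(pred) == 0:
        return {"rmse": rmse, "r2": 0.0}
    r = np.corrcoef(obs, pred)[0, 1]
    return {"rmse": rmse, "r2": float(r**2)}


def r2m(observed, predicted, direction: str = "pred_on_obs") -> float:
    """The r2m congruence statistic between observed and predicted values.

    With ``r2`` the squared Pearson correlation and ``r0_2`` the
    through-origin coefficient of determination of the regression of
    predicted on observed (slope ``k = sum(obs*pred)/sum(obs^2)``)::

        r2m = r2 * (1 - sqrt(|r2 - r0_2|))

    Predictions that track the observations only up to a bias or a gain
    give ``r0_2 < r2`` and are penalised.  ``direction="obs_on_pred"``
    swaps the roles (the reverse-variant convention).  The result is
    clamped at 0; strongly incongruent predictions can drive the raw
    expression negative.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if direction == "obs_on_pred":
        obs, pred = pred, obs
    elif direction != "pred_on_obs":
        raise ValueError(f"unknown r2m direction {direction!r}")
    if np.ptp(pred) == 0:
        raise ValueError("r2m is undefined for a constant predicted vector")
    if np.ptp(obs) == 0:
        raise ValueError("r2m is undefined for a constant observed vector")
    r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    k = float(np.sum(obs * pred) / np.sum(obs**2))
    ss_origin = float(np.sum((pred - k * obs) ** 2))
    ss_tot = float(np.sum((pred - pred.mean()) ** 2))
    r0_2 = 1.0 - ss_origin / ss_tot
    return float(max(0.0, r2 * (1.0 - np.sqrt(abs(r2 - r0_2)))))


def r2p(r2_cal: float, r2_rand_mean: float) -> float:
    """y-randomization summary ``sqrt(R2_cal) * sqrt(R2_cal - mean R2_rand)``.

    Values >= 0.5 indicate the calibration fit is well separated from
    chance-level fits; the result is clamped to 0 when the mean randomized
    R-squared reaches the calibration R-squared.
    """
    radicand = r2_cal - r2_rand_mean
    if radicand <= 0 or r2_cal <= 0:
        return 0.0
    return float(np.sqrt(r2_cal) * np.sqrt(radicand))


def y_randomization(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 100,
    seed: int | None = None,
    r2_cal: float | None = None,
) -> dict:
    """Response-permutation test of an MLR calibration.

    For each of ``n_perm`` permutations the response is shuffled, the model
    refitted, and the in-sample RMSE and R-squared recorded; their means
    estimate the chance-level fit.  ``r2_cal`` (computed from the
    unpermuted fit when omitted) feeds the :func:`r2p` summary.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    if r2_cal is None:
        base = fit_mlr(X, y)
        r2_cal = rmse_and_r2(y, predict(base, X))["r2"]
    rmses = np.empty(n_perm)
    r2s = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        model = fit_mlr(X, y_perm)
        stats = rmse_and_r2(y_perm, predict(model, X))
        rmses[i] = stats["rmse"]
        r2s[i] = stats["r2"]
    return {
        "rmse_mean": float(rmses.mean()),
        "r2_mean": float(r2s.mean()),
        "r2p": r2p(r2_cal, float(r2s.mean())),
    }


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    scheme: str = "loo",
    n_splits: int = 5,
    seed: int | None = None,
) -> dict:
    """Cross-validated RMSE and R-squared of the MLR.

    ``scheme="loo"`` (default) predicts each sample from a model fit on the
    remaining n - 1; ``scheme="kfold"`` uses seeded shuffled k-fold.
    Statistics are computed on the pooled held-out predictions.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("cross-validation needs at least 3 samples")
    if scheme == "loo":
        splitter = LeaveOneOut()
    elif scheme == "kfold":
        splitter = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    else:
        raise ValueError(f"unknown cross-validation scheme {scheme!r}")
    held_out = np.empty_like(y)
    for fold, (train, test) in enumerate(splitter.split(X)):
        try:
            model = fit_mlr(X[train], y[train])
        except SingularDesignError as err:
            raise SingularDesignError(f"fold {fold}: {err}") from err
        held_out[test] = predict(model, X[test])
    return rmse_and_r2(y, held_out)


# ---------------------------------------------------------------------------
# The full primary-model pipeline
# ---------------------------------------------------------------------------

def evaluate_primary(
    dataset: BlendDataset,
    descriptor_set: DescriptorSet | str,
    correction: CorrectionMethod | str,
    *,
    cal_fraction: float = 0.8,
    scheme: str = "systematic",
    seed: int | None = None,
    n_perm: int = 100,
    cv_scheme: str = "loo",
    blank_scope: str = "all",
    epsilon: float = 1e-6,
) -> tuple[MLRModel, ValidationReport]:
    """Fit and fully validate one primary model.

    Pipeline: compute the primary mean blank (from all samples by default,
    ``blank_scope="calibration"`` restricts it to the calibration subset),
    apply the lighting correction, project onto the descriptor subset,
    split, fit OLS on the calibration rows, and assemble calibration,
    leave-one-out cross-validation, y-randomization and external
    (hold-out) statistics.  The returned model carries the correction and
    stored primary blank so it can be applied to secondary-condition data.
    """
    descriptor_set = DescriptorSet(descriptor_set)
    correction = CorrectionMethod(correction)
    ss = np.random.SeedSequence(seed)
    split_seed, perm_seed = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))

    cal_idx, test_idx = split_indices(dataset.fractions, cal_fraction, scheme, split_seed)

    primary = None
    if correction.needs_primary_blank:
        scope = dataset if blank_scope == "all" else dataset.subset(cal_idx)
        primary = primary_blank_mean(scope)

    corrected = apply_correction(dataset, correction, primary, epsilon)
    X = descriptor_matrix(corrected, descriptor_set)
    y = dataset.fractions

    model = fit_mlr(
        X[cal_idx],
        y[cal_idx],
        descriptor_set=descriptor_set,
        correction=correction,
        primary_blank=primary,
        training_meta={
            "scheme": scheme,
            "cal_fraction": cal_fraction,
            "seed": seed,
            "n_cal": int(len(cal_idx)),
            "condition": dataset.metadata.get("condition"),
            "mixture": dataset.metadata.get("mixture"),
            "blank_scope": blank_scope,
        },
    )

    pred_cal = predict(model, X[cal_idx])
    calibration = rmse_and_r2(y[cal_idx], pred_cal)
    cv = cross_validate(X[cal_idx], y[cal_idx], scheme=cv_scheme, seed=perm_seed)
    yrand = y_randomization(
        X[cal_idx], y[cal_idx], n_perm=n_perm, seed=perm_seed, r2_cal=calibration["r2"]
    )
    pred_test = predict(model, X[test_idx])
    external = rmse_and_r2(y[test_idx], pred_test)
    external["r2m"] = r2m(y[test_idx], pred_test)

    report = ValidationReport(
        calibration=calibration,
        cross_validation=cv,
        y_randomization=yrand,
        external=external,
    )
    return model, report
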