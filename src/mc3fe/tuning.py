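"""Grid-search tuning of region factors and tuned-vs-untuned validation.

Tuning replicates the inverse procedure used to calibrate the material
model: for each specimen, the forward pipeline is evaluated over an
exhaustive factor grid (the mesh is reused; only the material model is
updated per candidate) and the candidate whose predicted mean PSG strain
is closest to the measured target wins.  Ties — the paper-style objective
is silent on them — go to the smallest-magnitude factor, i.e. the least
departure from the unmodified density–modulus law, and any tie-break is
recorded on the result.

The adaptive factor is then regressed on the normalized sclerotic volume
(a_scl = slope * v_scl + intercept) and the damage factors are pooled by
arithmetic mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import AsclLaw, RegionFactors, ascl_from_vscl
from .errors import DegenerateFitError, InvalidInputError

__all__ = [
    "TuningGrid",
    "ValidationReport",
    "ASCL_GRID",
    "DLYS_GRID",
    "tune_ascl",
    "tune_dlys",
    "fit_ascl_law",
    "pool_dlys",
    "validate",
]

#: Exhaustive adaptive-factor grid: -1.00 .. 0.50 at 0.05 steps (31 values,
#: endpoints inclusive).
ASCL_GRID = tuple(np.round(np.arange(-1.00, 0.50 + 1e-9, 0.05), 10))
#: Exhaustive damage-factor grid: 0.50 .. 0.95 at 0.05 steps (10 values).
DLYS_GRID = tuple(np.round(np.arange(0.50, 0.95 + 1e-9, 0.05), 10))


@dataclass
class TuningGrid:
    """Exhaustive grid-search result for one factor on one specimen."""

    candidate_values: np.ndarray
    predicted: np.ndarray  # predicted mean PSG strain per candidate
    objective: np.ndarray  # |predicted - target| per candidate
    optimum: float
    tie_rule: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "candidate": self.candidate_values,
                "predicted_psg_strain": self.predicted,
                "objective": self.objective,
            }
        )


def _select_optimum(candidates: np.ndarray, objective: np.ndarray) -> tuple[float, str | None]:
    best = objective.min()
    ties = candidates[objective == best]
    if ties.size == 1:
        return float(ties[0]), None
    # least modification of the unmodified law wins; magnitude ties break low
    order = np.lexsort((ties, np.abs(ties)))
    chosen = float(ties[order[0]])
    return chosen, (
        f"{ties.size} candidates tied at objective {best:.6g}; "
        f"chose smallest-magnitude factor {chosen}"
    )


def _run_grid(forward, candidates, target_strain: float, make_factors) -> TuningGrid:
    cands = np.asarray(candidates, dtype=float)
    if cands.size < 1:
        raise InvalidInputError("candidate grid is empty")
    if target_strain <= 0:
        raise InvalidInputError("target_strain must be positive")
    predicted = np.array([forward(make_factors(c)) for c in cands])
    objective = np.abs(predicted - target_strain)
    optimum, tie_rule = _select_optimum(cands, objective)
    return TuningGrid(
        candidate_values=cands,
        predicted=predicted,
        objective=objective,
        optimum=optimum,
        tie_rule=tie_rule,
    )


def tune_ascl(
    specimen,
    target_strain: float,
    candidates=ASCL_GRID,
    d_lys: float = 0.0,
) -> TuningGrid:
    """Tune the sclerotic adaptive factor against a measured PSG strain.

    ``specimen`` must expose ``forward(RegionFactors) -> float`` (the full
    forward pipeline on a fixed mesh) and a truthy sclerotic region
    (``has_sclerosis`` on its solver, when available).  ``d_lys`` is held
    fixed across the grid.
    """
    solver = getattr(specimen, "solver", specimen)
    if hasattr(solver, "has_sclerosis") and not solver.has_sclerosis:
        raise InvalidInputError("specimen has no sclerotic region to tune")
    forward = specimen.forward if hasattr(specimen, "forward") else specimen.psg_strain
    return _run_grid(forward, candidates, target_strain, lambda a: RegionFactors(a, d_lys))


def tune_dlys(
    specimen,
    target_strain: float,
    candidates=DLYS_GRID,
    a_scl: float | AsclLaw | None = None,
) -> TuningGrid:
    """Tune the lytic damage factor against a measured PSG strain.

    The sclerotic factor is held at ``a_scl`` during the search: pass a
    float, an :class:`AsclLaw` (evaluated at the specimen's ``v_scl``), or
    None for the default law.  Requires a lytic region.
    """
    solver = getattr(specimen, "solver", specimen)
    if hasattr(solver, "has_lysis") and not solver.has_lysis:
        raise InvalidInputError("specimen has no lytic region to tune")
    if a_scl is None:
        a_scl = AsclLaw()
    if isinstance(a_scl, AsclLaw):
        v_scl = getattr(specimen, "v_scl", None)
        if v_scl is None:
            raise InvalidInputError("specimen lacks v_scl; pass a_scl as a float instead")
        a_val = float(ascl_from_vscl(v_scl, a_scl))
    else:
        a_val = float(a_scl)
    forward = specimen.forward if hasattr(specimen, "forward") else specimen.psg_strain
    return _run_grid(forward, candidates, target_strain, lambda d: RegionFactors(a_val, d))


def fit_ascl_law(pairs) -> AsclLaw:
    """OLS fit of optimal a_scl on v_scl over the tuning specimens."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DegenerateFitError("need at least two (v_scl, a_scl) pairs")
    v, a = arr[:, 0], arr[:, 1]
    if np.unique(v).size < 2:
        raise DegenerateFitError("v_scl values must not be all identical")
    slope, intercept = np.polyfit(v, a, 1)
    return AsclLaw(slope=float(slope), intercept=float(intercept))


def pool_dlys(optima) -> float:
    """Pooled damage factor: the arithmetic mean of the per-specimen optima."""
    arr = np.asarray(optima, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cannot pool an empty list of optima")
    return float(arr.mean())


@dataclass
class ValidationReport:
    """Per-specimen and aggregate agreement of predicted vs measured strain."""

    table: pd.DataFrame  # columns: id, group, predicted, measured, abs_difference
    regression_slope: float | None
    regression_intercept: float | None
    r_squared: float | None
    mean_relative_error_pct: float

    def to_dict(self) -> dict:
        return {
            "specimens": self.table.to_dict(orient="records"),
            "regression_slope": self.regression_slope,
            "regression_intercept": self.regression_intercept,
            "r_squared": self.r_squared,
            "mean_relative_error_pct": self.mean_relative_error_pct,
        }


def _report(ids, groups, predicted, measured) -> ValidationReport:
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    table = pd.DataFrame(
        {
            "id": ids,
            "group": groups,
            "predicted": predicted,
            "measured": measured,
            "abs_difference": np.abs(predicted - measured),
        }
    )
    mre = float(np.mean(np.abs(predicted - measured) / measured) * 100.0)
    if len(table) >= 3:
        res = stats.linregress(measured, predicted)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
    else:
        warnings.warn("fewer than 3 specimens: regression skipped", stacklevel=3)
        slope = intercept = r2 = None
    return ValidationReport(
        table=table,
        regression_slope=slope,
        regression_intercept=intercept,
        r_squared=r2,
        mean_relative_error_pct=mre,
    )


def validate(
    specimens,
    ascl_law: AsclLaw,
    pooled_dlys: float,
    untuned: RegionFactors = RegionFactors(0.0, 0.0),
) -> tuple[ValidationReport, ValidationReport]:
    """Run tuned and untuned forward predictions over held-out specimens.

    Each specimen must expose ``forward(RegionFactors) -> float``,
    ``measured_strain > 0``, ``v_scl``, ``specimen_id``, ``group`` and
    ``has_lysis``.  The tuned model uses ``a_scl = ascl_law(v_scl)`` and
    ``d_lys = pooled_dlys`` in specimens with a lytic region; the untuned
    model uses the unmodified density–modulus law.  Returns
    ``(tuned_report, untuned_report)``.
    """
    specimens = list(specimens)
    if not specimens:
        raise InvalidInputError("no specimens to validate")
    ids, groups, meas = [], [], []
    pred_tuned, pred_untuned = [], []
    for s in specimens:
        if s.measured_strain <= 0:
            raise InvalidInputError(f"specimen {s.specimen_id}: measured strain must be positive")
        a = float(ascl_from_vscl(s.v_scl, ascl_law))
        d = float(pooled_dlys) if s.has_lysis else 0.0
        ids.append(s.specimen_id)
        groups.append(s.group)
        meas.append(s.measured_strain)
        pred_tuned.append(s.forward(RegionFactors(a, d)))
        pred_untuned.append(s.forward(untuned))
    return _report(ids, groups, pred_tuned, meas), _report(ids, groups, pred_untuned, meas)
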