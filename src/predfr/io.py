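"""CSV input/output and the end-to-end analysis report.

Input schemas (UTF-8 CSV with header):

``trials.csv``
    predator,prey_stage,density,consumed,replicate with
    prey_stage in {nymph_4_5, adult}.
``detection.csv``
    order,family,species,n_collected,n_detected,n_positive.

:func:`run_full_analysis` binds the pipeline together per predator x stage:
cubic type determination -> classification -> disc-equation fit (model taken
from the classification unless overridden) -> derived metrics -> search
curve, plus detection and composition summaries when a detection table is
supplied. A failure in one group is recorded in the report instead of
aborting the run.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from ._rounding import round_half_up
from .errors import InvalidInputError, ValidationError
from .functional_response import (
    HollingFit,
    PolyTypeFit,
    PredationTrial,
    PreyStage,
    ResponseType,
    SearchCurve,
    TrialSet,
    derived_metrics,
    fit_holling,
    fit_polynomial_type,
    search_efficiency,
)
from .gut_detection import (
    CompositionSummary,
    DetectionRecord,
    DetectionSummary,
    DetectionTable,
    community_composition,
    summarize_detection,
)

__all__ = [
    "read_trials",
    "write_trials",
    "read_detection",
    "write_fits_csv",
    "write_type_csv",
    "GroupResult",
    "AnalysisReport",
    "run_full_analysis",
]

TRIALS_COLUMNS = ["predator", "prey_stage", "density", "consumed", "replicate"]
DETECTION_COLUMNS = [
    "order", "family", "species", "n_collected", "n_detected", "n_positive",
]


def read_trials(path: str | Path) -> list[TrialSet]:
    """Read a trials CSV and group rows into TrialSets by (predator, stage).

    Row-level invariant violations are reported with the file name and the
    0-based data row index.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: empty input")
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")

    trials_by_group: dict[tuple[str, PreyStage], list[PredationTrial]] = {}
    for idx, row in df.iterrows():
        try:
            stage = PreyStage(str(row["prey_stage"]))
        except ValueError:
            raise ValidationError(
                f"{path}: row {idx}: unknown prey_stage {row['prey_stage']!r}"
            ) from None
        try:
            consumed = float(row["consumed"])
            if consumed.is_integer():
                consumed = int(consumed)  # keeps write_trials round-trip stable
            trial = PredationTrial(
                predator_id=str(row["predator"]),
                prey_stage=stage,
                density=int(row["density"]),
                consumed=consumed,
                replicate=int(row["replicate"]),
            )
        except (InvalidInputError, ValueError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from None
        trials_by_group.setdefault((trial.predator_id, stage), []).append(trial)

    return [
        TrialSet(predator_id=pred, prey_stage=stage, trials=tuple(ts))
        for (pred, stage), ts in trials_by_group.items()
    ]


def write_trials(trial_sets: list[TrialSet], path: str | Path) -> None:
    """Write TrialSets back to the trials.csv schema."""
    rows = [
        {
            "predator": t.predator_id,
            "prey_stage": t.prey_stage.value,
            "density": t.density,
            "consumed": t.consumed,
            "replicate": t.replicate,
        }
        for ts in trial_sets
        for t in ts.trials
    ]
    pd.DataFrame(rows, columns=TRIALS_COLUMNS).to_csv(path, index=False)


def read_detection(path: str | Path) -> DetectionTable:
    """Read a detection CSV into a DetectionTable, validating each row."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: empty input")
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                DetectionRecord(
                    order=str(row["order"]),
                    family=str(row["family"]),
                    species=str(row["species"]),
                    n_collected=int(row["n_collected"]),
                    n_detected=int(row["n_detected"]),
                    n_positive=int(row["n_positive"]),
                )
            )
        except (InvalidInputError, ValueError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from None
    return DetectionTable(records=tuple(records))


def write_fits_csv(fits: list[HollingFit], path: str | Path) -> None:
    """Write fitted parameters plus derived metrics, rounded for reporting."""
    rows = []
    for f in fits:
        dm = derived_metrics(f)
        rows.append(
            {
                "predator": f.predator_id,
                "prey_stage": f.prey_stage.value if f.prey_stage else "",
                "model": f.model.value,
                "a_prime": round_half_up(f.attack_rate, 3),
                "Th": round_half_up(f.handling_time, 3),
                "T": f.exposure_T,
                "r_squared": round_half_up(f.r_squared, 3),
                "T_over_Th": round_half_up(dm.daily_max_predation, 2),
                "aprime_over_Th": round_half_up(dm.theoretical_predation, 2),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_type_csv(
    fits: Mapping[tuple[str, str], PolyTypeFit], path: str | Path
) -> None:
    """Write cubic type-determination results keyed by (predator, stage)."""
    rows = [
        {
            "predator": pred,
            "prey_stage": stage,
            "a": pf.a, "b": pf.b, "c": pf.c, "d": pf.d,
            "r_squared": round_half_up(pf.r_squared, 3),
            "type": pf.response_type.value,
        }
        for (pred, stage), pf in fits.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class GroupResult:
    """Pipeline output for one predator x prey-stage group."""

    predator_id: str
    prey_stage: PreyStage
    poly_fit: PolyTypeFit | None = None
    holling_fit: HollingFit | None = None
    search_curve: SearchCurve | None = None
    error: str | None = None


@dataclass(frozen=True)
class AnalysisReport:
    """Full pipeline output plus a provenance block.

    Derived metrics in the JSON form are recomputed from each fit's
    (a', Th, T), so they are consistent with the parameters by construction.
    """

    groups: tuple[GroupResult, ...]
    detection: DetectionSummary | None
    composition: CompositionSummary | None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        """JSON-serialisable report with full-precision values."""
        out: dict[str, Any] = {"groups": [], "provenance": dict(self.provenance)}
        for g in self.groups:
            entry: dict[str, Any] = {
                "predator": g.predator_id,
                "prey_stage": g.prey_stage.value,
            }
            if g.error is not None:
                entry["error"] = g.error
            if g.poly_fit is not None:
                pf = g.poly_fit
                entry["type_fit"] = {
                    "a": pf.a, "b": pf.b, "c": pf.c, "d": pf.d,
                    "se_b": pf.se_b, "r_squared": pf.r_squared,
                    "response_type": pf.response_type.value,
                }
            if g.holling_fit is not None:
                f = g.holling_fit
                dm = derived_metrics(f)
                entry["holling_fit"] = {
                    "model": f.model.value,
                    "attack_rate": f.attack_rate,
                    "handling_time": f.handling_time,
                    "exposure_T": f.exposure_T,
                    "r_squared": f.r_squared,
                    "n_points": f.n_points,
                    "converged": f.converged,
                    "warnings": list(f.warnings),
                    "daily_max_predation": dm.daily_max_predation,
                    "theoretical_predation": dm.theoretical_predation,
                }
            if g.search_curve is not None:
                entry["search_curve"] = {
                    "densities": list(g.search_curve.densities),
                    "efficiency": list(g.search_curve.efficiency),
                }
            out["groups"].append(entry)
        if self.detection is not None:
            d = self.detection
            out["detection"] = {
                "pooled_rate": d.pooled_rate,
                "per_taxon_rate": dict(d.per_taxon_rate),
                "positive_taxa": list(d.positive_taxa),
                "total_collected": d.total_collected,
                "total_detected": d.total_detected,
                "total_positive": d.total_positive,
                "extraction_failures": d.extraction_failures,
            }
        if self.composition is not None:
            c = self.composition
            out["composition"] = {
                "grand_total": c.grand_total,
                "per_species": [list(row) for row in c.per_species],
                "per_class": [list(row) for row in c.per_class],
            }
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(
    trials_path: str | Path,
    detection_path: str | Path | None = None,
    *,
    model: str = "auto",
    aggregate: str = "raw",
    exposure_T: float = 1.0,
    search_densities: tuple[float, ...] = (5, 10, 15, 20, 25, 30),
    seed: int | None = None,
) -> AnalysisReport:
    """Run the end-to-end analysis from CSV inputs.

    ``model="auto"`` takes the disc-equation form from the cubic type call
    for each group (an indeterminate call falls back to Type II, flagged in
    the group error field); ``"II"``/``"III"`` force a form.
    """
    trials_path = Path(trials_path)
    trial_sets = read_trials(trials_path)

    groups: list[GroupResult] = []
    for ts in trial_sets:
        try:
            poly = fit_polynomial_type(ts)
            note = None
            if model == "auto":
                chosen = poly.response_type
                if chosen is ResponseType.INDETERMINATE:
                    chosen = ResponseType.II
                    note = "type call indeterminate (b == 0); fitted Type II"
            else:
                chosen = ResponseType(model)
            fit = fit_holling(ts, model=chosen, exposure_T=exposure_T,
                              aggregate=aggregate)
            curve = search_efficiency(fit, search_densities)
            groups.append(
                GroupResult(
                    predator_id=ts.predator_id,
                    prey_stage=ts.prey_stage,
                    poly_fit=poly,
                    holling_fit=fit,
                    search_curve=curve,
                    error=note,
                )
            )
        except Exception as exc:  # partial completion: record, keep going
            groups.append(
                GroupResult(
                    predator_id=ts.predator_id,
                    prey_stage=ts.prey_stage,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )

    detection = composition = None
    if detection_path is not None:
        table = read_detection(detection_path)
        detection = summarize_detection(table)
        from .datasets import ORDER_TO_CLASS

        composition = community_composition(
            (ORDER_TO_CLASS.get(r.order, r.order), r.species, r.n_collected)
            for r in table.records
        )

    provenance = {
        "version": __version__,
        "seed": seed,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "inputs": {
            "trials": {"path": str(trials_path), "sha256": _sha256(trials_path)},
        },
        "options": {
            "model": model, "aggregate": aggregate, "exposure_T": exposure_T,
        },
    }
    if detection_path is not None:
        provenance["inputs"]["detection"] = {
            "path": str(detection_path),
            "sha256": _sha256(Path(detection_path)),
        }

    return AnalysisReport(
        groups=tuple(groups),
        detection=detection,
        composition=composition,
        provenance=provenance,
    )
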