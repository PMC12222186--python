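"""Aggregation and derivation of the three effect-size quantities.

From each validated observation this module derives:

* **relative EC** — stress-treatment EC minus control EC (dS/m), which sets
  every study's control baseline to zero so that soil-salinity and
  solution-salinity studies are comparable;
* **stress integral** — relative EC x stress duration (dS.day/m), a better
  stress axis for growth measured at the vegetative stage, where how long the
  plants were stressed matters as much as how hard;
* **relative response** — stress mean / control mean, the dimensionless
  response ratio (1 = no effect, < 1 = stress-induced decrease).

It also implements the two corpus-level rules applied before analysis:
unweighted averaging of genotype/year replicate rows, and the
effective-stress gate that keeps only (study, experiment, salinity level)
groups where the salt decreased shoot dry weight or grain yield.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import (
    ObservationRecord,
    SalinityMeasure,
    Setting,
    Stage,
    ValidationError,
    Variable,
    VariableKey,
)

__all__ = [
    "StressAxis",
    "RelativeObservation",
    "AggregationError",
    "aggregate_replicates",
    "derive_relative",
    "derive_all",
    "filter_effective_stress",
    "resolve_duration",
    "relatives_to_frame",
    "write_derived",
]


class AggregationError(ValueError):
    """Rows that should be averaged together are mutually inconsistent."""


class StressAxis(str, enum.Enum):
    """Which stress quantity an observation is analyzed against."""

    RELATIVE_EC = "relative_ec"
    STRESS_INTEGRAL = "stress_integral"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class RelativeObservation:
    """A derived effect row: the response ratio against its stress axis."""

    study_id: str
    experiment_id: str
    setting: Setting
    variable: VariableKey
    relative_ec: float
    relative_response: float
    stress_integral: float | None
    stress_axis: StressAxis

    def __post_init__(self) -> None:
        if not (self.relative_ec > 0):
            raise ValidationError(
                f"relative_ec must be positive, got {self.relative_ec}"
            )
        if not math.isfinite(self.relative_response) or self.relative_response < 0:
            raise ValidationError(
                f"relative_response must be finite and >= 0, got "
                f"{self.relative_response}"
            )

    @property
    def axis_value(self) -> float | None:
        """Value on the observation's stress axis; ``None`` when the axis is
        the stress integral but no duration was recorded."""
        if self.stress_axis is StressAxis.STRESS_INTEGRAL:
            return self.stress_integral
        return self.relative_ec


def resolve_duration(
    explicit_days: float | None = None,
    start_day: float | None = None,
    measurement_day: float | None = None,
) -> float | None:
    """Stress duration in days: an explicit value wins; otherwise the span
    from stress start to measurement (salt is assumed to persist once applied
    unless the study flushed it, in which case the explicit value should be
    given)."""
    if explicit_days is not None:
        if explicit_days <= 0:
            raise ValidationError("stress duration must be positive")
        return explicit_days
    if start_day is not None and measurement_day is not None:
        days = measurement_day - start_day
        if days <= 0:
            raise ValidationError(
                "measurement day must come after stress start day"
            )
        return days
    return None


def _group_key(r: ObservationRecord):
    return (
        r.study_id,
        r.experiment_id,
        r.setting,
        r.variable,
        r.control_salinity.value,
        r.stress_salinity.value,
    )


def aggregate_replicates(
    records: Sequence[ObservationRecord],
) -> list[ObservationRecord]:
    """Average genotype/year replicate rows within each
    (study, experiment, setting, variable, salinity level) group.

    The mean is unweighted and applied to control and stress values alike;
    singleton groups pass through unchanged.  Rows in one group must report
    salinity in the same unit — a mixed group is an error rather than a
    silent conversion, because identical numeric levels in different units
    are different treatments.
    """
    groups: dict[tuple, list[ObservationRecord]] = {}
    order: list[tuple] = []
    for r in records:
        k = _group_key(r)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(r)

    out: list[ObservationRecord] = []
    for k in order:
        members = groups[k]
        if len(members) == 1:
            out.append(members[0])
            continue
        units = {
            (m.control_salinity.unit, m.stress_salinity.unit) for m in members
        }
        if len(units) > 1:
            raise AggregationError(
                f"group {k[:4]} at level {k[4]}/{k[5]} mixes salinity units: "
                f"{sorted(u[1].value for u in units)}"
            )
        basis = {m.concentration_basis for m in members}
        if len(basis) > 1:
            raise AggregationError(
                f"group {k[:4]} mixes concentration bases {sorted(map(str, basis))}"
            )
        first = members[0]
        n = len(members)
        out.append(
            replace(
                first,
                control_value=sum(m.control_value for m in members) / n,
                stress_value=sum(m.stress_value for m in members) / n,
                year_label=None,
                n_genotypes=None,
            )
        )
    return out


def derive_relative(record: ObservationRecord) -> RelativeObservation:
    """Derive the effect row for one record.

    The stress axis is the stress integral exactly for vegetative-stage
    growth variables and the relative EC otherwise.
    """
    relative_ec = record.stress_ec - record.control_ec
    if relative_ec <= 0:
        raise ValidationError(
            f"relative EC must be positive, got {relative_ec:g} dS/m"
        )
    if record.control_value <= 0:
        raise ValidationError("control_value must be positive")
    duration = record.stress_duration_days
    integral = relative_ec * duration if duration is not None else None
    axis = (
        StressAxis.STRESS_INTEGRAL
        if record.variable.is_growth and record.variable.stage is Stage.VEGETATIVE
        else StressAxis.RELATIVE_EC
    )
    return RelativeObservation(
        study_id=record.study_id,
        experiment_id=record.experiment_id,
        setting=record.setting,
        variable=record.variable,
        relative_ec=relative_ec,
        relative_response=record.stress_value / record.control_value,
        stress_integral=integral,
        stress_axis=axis,
    )


def derive_all(
    records: Sequence[ObservationRecord],
) -> tuple[list[RelativeObservation], list[str]]:
    """Derive effect rows for all analyzable records.

    Fresh-weight metabolite rows are skipped (with a note), honouring the
    dry-weight-only rule for tissue concentrations.
    """
    out: list[RelativeObservation] = []
    notes: list[str] = []
    for r in records:
        if r.analysis_excluded:
            notes.append(
                f"{r.study_id}/{r.experiment_id} {r.variable.label()}: "
                "fresh-weight metabolite row excluded from analysis"
            )
            continue
        out.append(derive_relative(r))
    return out, notes


_ANCHOR_VARIABLES = {Variable.SHOOT_DW, Variable.GRAIN_YIELD}


def filter_effective_stress(
    observations: Sequence[RelativeObservation],
    missing_anchor_policy: str = "keep",
) -> tuple[list[RelativeObservation], list[str]]:
    """Keep only salinity levels where the salt actually depressed growth.

    A (study, experiment, salinity level) group is retained when at least one
    of its shoot-dry-weight or grain-yield response ratios is below 1 — the
    stress must have induced a decrease in *either* anchor.  Groups whose
    anchors all sit at or above 1 are dropped and reported.  Groups lacking
    both anchors follow ``missing_anchor_policy``: ``"keep"`` (default,
    with a warning) or ``"drop"``.
    """
    if missing_anchor_policy not in ("keep", "drop"):
        raise ValueError("missing_anchor_policy must be 'keep' or 'drop'")
    keys = [
        (o.study_id, o.experiment_id, round(o.relative_ec, 9)) for o in observations
    ]
    anchors: dict[tuple, list[float]] = {}
    for o, k in zip(observations, keys):
        if o.variable.name in _ANCHOR_VARIABLES:
            anchors.setdefault(k, []).append(o.relative_response)

    kept: list[RelativeObservation] = []
    report: list[str] = []
    dropped: set[tuple] = set()
    warned: set[tuple] = set()
    for o, k in zip(observations, keys):
        ratios = anchors.get(k)
        if ratios is None:
            if k not in warned:
                warned.add(k)
                report.append(
                    f"group {k}: no shoot_dw or grain_yield anchor; policy="
                    f"{missing_anchor_policy}"
                )
            if missing_anchor_policy == "drop":
                continue
        elif min(ratios) >= 1.0:
            if k not in dropped:
                dropped.add(k)
                report.append(
                    f"group {k}: dropped, no decrease in shoot_dw or grain_yield "
                    f"(min anchor ratio {min(ratios):.3g})"
                )
            continue
        kept.append(o)
    return kept, report


def relatives_to_frame(
    observations: Iterable[RelativeObservation],
) -> pd.DataFrame:
    """Long-format table of derived effect rows, one per observation."""
    rows = []
    for o in observations:
        rows.append(
            {
                "study_id": o.study_id,
                "experiment_id": o.experiment_id,
                "setting": o.setting.value,
                "variable": o.variable.name.value,
                "stage": o.variable.stage.value,
                "method_tag": o.variable.method_tag or None,
                "relative_ec": o.relative_ec,
                "stress_integral": o.stress_integral,
                "relative_response": o.relative_response,
                "stress_axis": o.stress_axis.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "study_id",
            "experiment_id",
            "setting",
            "variable",
            "stage",
            "method_tag",
            "relative_ec",
            "stress_integral",
            "relative_response",
            "stress_axis",
        ],
    )


def write_derived(
    observations: Sequence[RelativeObservation], path: str | Path
) -> None:
    relatives_to_frame(observations).to_csv(path, index=False)
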