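"""Observation data model, salinity unit conversion, and corpus file I/O.

A *corpus* is a delimited (CSV, UTF-8) table with one row per study-level
measurement pair: the mean of a variable under a control (low-salinity)
treatment and under a saline treatment, together with the salinity of both
treatments, the experimental setting, and assorted metadata.  Salinity may be
reported as electrical conductivity (dS/m), molar NaCl concentration, or ppm
NaCl; everything downstream works on EC, so conversion lives here.

Rows that violate the data model are never silently dropped: :func:`read_corpus`
returns both the valid records and a rejection report with one entry per bad
row.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Setting",
    "Variable",
    "Stage",
    "SalinityUnit",
    "SalinityMeasure",
    "VariableKey",
    "ObservationRecord",
    "Rejection",
    "RejectionReport",
    "ValidationError",
    "SchemaError",
    "EC_PER_MOLAR_NACL",
    "EC_PER_1000PPM_NACL",
    "ec_from_unit",
    "parse_salinity",
    "read_corpus",
    "write_corpus",
    "load_column_map",
    "CORPUS_COLUMNS",
    "GROWTH_VARIABLES",
    "METABOLITE_VARIABLES",
]


class ValidationError(ValueError):
    """A record or value violates the observation data model."""


class SchemaError(ValueError):
    """A corpus file does not match the documented column schema."""


class Setting(str, enum.Enum):
    """The four admissible experimental settings."""

    FIELD = "field"
    OUTDOOR_POTS = "outdoor_pots"
    GREENHOUSE = "greenhouse"
    CLIMATE_CHAMBER = "climate_chamber"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Variable(str, enum.Enum):
    """Response variables tracked by the meta-analysis."""

    HEIGHT = "height"
    SHOOT_DW = "shoot_dw"
    ROOT_DW = "root_dw"
    GRAIN_YIELD = "grain_yield"
    TKW = "tkw"
    N_SPIKES = "n_spikes"
    N_GRAINS = "n_grains"
    CHLOROPHYLL = "chlorophyll"
    PROLINE = "proline"
    SODIUM = "sodium"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Growth variables carry a developmental-stage subvariable (vegetative vs
#: reproductive); all other variables have stage ``none``.
GROWTH_VARIABLES = frozenset({Variable.HEIGHT, Variable.SHOOT_DW, Variable.ROOT_DW})

#: Tissue-concentration variables subject to the dry-weight-basis rule.
METABOLITE_VARIABLES = frozenset(
    {Variable.CHLOROPHYLL, Variable.PROLINE, Variable.SODIUM}
)


class Stage(str, enum.Enum):
    VEGETATIVE = "vegetative"
    REPRODUCTIVE = "reproductive"
    NONE = "none"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SalinityUnit(str, enum.Enum):
    DS_PER_M = "dS_per_m"
    MOL_PER_L_NACL = "mol_per_L_NaCl"
    PPM_NACL = "ppm_NaCl"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: 1 M NaCl is equivalent to 98 dS/m.
EC_PER_MOLAR_NACL = 98.0
#: 1000 ppm NaCl is equivalent to 1.66 dS/m.
EC_PER_1000PPM_NACL = 1.66

_EC_FACTOR = {
    SalinityUnit.DS_PER_M: 1.0,
    SalinityUnit.MOL_PER_L_NACL: EC_PER_MOLAR_NACL,
    SalinityUnit.PPM_NACL: EC_PER_1000PPM_NACL / 1000.0,
}

_UNIT_ALIASES = {
    "ds_per_m": (SalinityUnit.DS_PER_M, 1.0),
    "ds/m": (SalinityUnit.DS_PER_M, 1.0),
    "dsm-1": (SalinityUnit.DS_PER_M, 1.0),
    "ds m-1": (SalinityUnit.DS_PER_M, 1.0),
    "mol_per_l_nacl": (SalinityUnit.MOL_PER_L_NACL, 1.0),
    "mol/l": (SalinityUnit.MOL_PER_L_NACL, 1.0),
    "m": (SalinityUnit.MOL_PER_L_NACL, 1.0),
    "mm": (SalinityUnit.MOL_PER_L_NACL, 1e-3),
    "ppm_nacl": (SalinityUnit.PPM_NACL, 1.0),
    "ppm": (SalinityUnit.PPM_NACL, 1.0),
}


def _resolve_unit(token: str) -> tuple[SalinityUnit, float]:
    """Map a unit spelling to the canonical unit and a value multiplier.

    ``mM`` resolves to mol/L with a 1e-3 multiplier so that e.g. ``150 mM``
    becomes ``SalinityMeasure(0.15, mol_per_L_NaCl)``.
    """
    key = token.strip().lower()
    if key not in _UNIT_ALIASES:
        raise ValidationError(f"unknown salinity unit {token!r}")
    return _UNIT_ALIASES[key]


def ec_from_unit(value: float, unit: SalinityUnit | str) -> float:
    """Convert a salinity measurement to electrical conductivity in dS/m.

    Conversion is linear: dS/m passes through, mol/L NaCl scales by 98,
    ppm NaCl by 1.66/1000.
    """
    if isinstance(unit, str) and not isinstance(unit, SalinityUnit):
        unit, mult = _resolve_unit(unit)
        value = value * mult
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValidationError("salinity value is missing")
    if value < 0:
        raise ValidationError(f"salinity value must be non-negative, got {value}")
    try:
        factor = _EC_FACTOR[SalinityUnit(unit)]
    except ValueError as exc:
        raise ValidationError(f"unknown salinity unit {unit!r}") from exc
    return value * factor


@dataclass(frozen=True)
class SalinityMeasure:
    """A salinity value with its reporting unit."""

    value: float
    unit: SalinityUnit

    def __post_init__(self) -> None:
        if self.value < 0 or math.isnan(self.value):
            raise ValidationError(
                f"salinity value must be non-negative, got {self.value}"
            )
        object.__setattr__(self, "unit", SalinityUnit(self.unit))

    def to_ec(self) -> float:
        """This measurement expressed as EC in dS/m."""
        return ec_from_unit(self.value, self.unit)


_SALINITY_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s*(.+?)\s*$")


def parse_salinity(text: str) -> SalinityMeasure:
    """Parse a free-text salinity such as ``"150 mM"`` or ``"12 dS/m"``.

    Millimolar values are folded into mol/L, so ``"150 mM"`` yields
    ``SalinityMeasure(0.15, mol_per_L_NaCl)``.
    """
    m = _SALINITY_RE.match(text)
    if m is None:
        raise ValidationError(f"cannot parse salinity {text!r}")
    unit, mult = _resolve_unit(m.group(2))
    return SalinityMeasure(float(m.group(1)) * mult, unit)


@dataclass(frozen=True)
class VariableKey:
    """A response variable plus its developmental-stage subvariable.

    ``method_tag`` is free text distinguishing measurement methods (e.g. SPAD
    vs biochemical chlorophyll, yield per plant vs per area); rows with
    different tags are never aggregated together.
    """

    name: Variable
    stage: Stage = Stage.NONE
    method_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", Variable(self.name))
        object.__setattr__(self, "stage", Stage(self.stage))
        if self.stage is not Stage.NONE and self.name not in GROWTH_VARIABLES:
            raise ValidationError(
                f"stage {self.stage.value!r} is only admissible for growth "
                f"variables, not {self.name.value!r}"
            )

    @property
    def is_growth(self) -> bool:
        return self.name in GROWTH_VARIABLES

    @property
    def is_metabolite(self) -> bool:
        return self.name in METABOLITE_VARIABLES

    def label(self) -> str:
        parts = [self.name.value]
        if self.stage is not Stage.NONE:
            parts.append(self.stage.value)
        if self.method_tag:
            parts.append(self.method_tag)
        return ":".join(parts)


class ConcentrationBasis(str, enum.Enum):
    DRY_WEIGHT = "dry_weight"
    FRESH_WEIGHT = "fresh_weight"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ObservationRecord:
    """One study-level (control mean, stress mean) measurement pair."""

    study_id: str
    experiment_id: str
    setting: Setting
    variable: VariableKey
    control_salinity: SalinityMeasure
    stress_salinity: SalinityMeasure
    control_value: float
    stress_value: float
    stress_duration_days: float | None = None
    concentration_basis: ConcentrationBasis | None = None
    n_genotypes: int | None = None
    year_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "setting", Setting(self.setting))
        if self.concentration_basis is not None:
            object.__setattr__(
                self,
                "concentration_basis",
                ConcentrationBasis(self.concentration_basis),
            )
        self.validate()

    def validate(self) -> None:
        if not self.study_id or not self.experiment_id:
            raise ValidationError("study_id and experiment_id are required")
        if math.isnan(self.control_value) or self.control_value <= 0:
            raise ValidationError(
                f"control_value must be > 0, got {self.control_value}"
            )
        if math.isnan(self.stress_value) or self.stress_value < 0:
            raise ValidationError(
                f"stress_value must be >= 0, got {self.stress_value}"
            )
        if self.stress_ec <= self.control_ec:
            raise ValidationError(
                "stress salinity must exceed control salinity as EC "
                f"({self.stress_ec:g} <= {self.control_ec:g} dS/m)"
            )
        if self.stress_duration_days is not None and self.stress_duration_days <= 0:
            raise ValidationError("stress_duration_days must be positive")
        if self.n_genotypes is not None and self.n_genotypes < 1:
            raise ValidationError("n_genotypes must be a positive integer")

    @property
    def control_ec(self) -> float:
        return self.control_salinity.to_ec()

    @property
    def stress_ec(self) -> float:
        return self.stress_salinity.to_ec()

    @property
    def analysis_excluded(self) -> bool:
        """Fresh-weight metabolite concentrations are kept for provenance but
        excluded from analysis: changes in tissue water content would confound
        a per-fresh-weight concentration."""
        return (
            self.variable.is_metabolite
            and self.concentration_basis is ConcentrationBasis.FRESH_WEIGHT
        )


@dataclass(frozen=True)
class Rejection:
    row: int  # 1-based data row number (header excluded)
    reason: str


@dataclass
class RejectionReport:
    rejections: list[Rejection] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rejections)

    def add(self, row: int, reason: str) -> None:
        self.rejections.append(Rejection(row, reason))


#: Canonical corpus columns, in file order.
CORPUS_COLUMNS = [
    "study_id",
    "experiment_id",
    "setting",
    "variable",
    "stage",
    "method_tag",
    "control_salinity_value",
    "control_salinity_unit",
    "stress_salinity_value",
    "stress_salinity_unit",
    "control_value",
    "stress_value",
    "stress_duration_days",
    "concentration_basis",
    "n_genotypes",
    "year_label",
]

_MANDATORY_COLUMNS = [
    "study_id",
    "experiment_id",
    "setting",
    "variable",
    "control_salinity_value",
    "control_salinity_unit",
    "stress_salinity_value",
    "stress_salinity_unit",
    "control_value",
    "stress_value",
]


def load_column_map(path: str | Path) -> dict[str, str]:
    """Read a ``theirs = ours`` key-value text file mapping third-party column
    names onto the canonical corpus schema.  Blank lines and ``#`` comments
    are ignored."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise SchemaError(f"malformed column-map line: {line!r}")
        theirs, ours = (tok.strip() for tok in line.split("=", 1))
        if ours not in CORPUS_COLUMNS:
            raise SchemaError(f"column-map target {ours!r} is not a corpus column")
        mapping[theirs] = ours
    return mapping


def _cell(row: pd.Series, name: str) -> str | None:
    if name not in row.index:
        return None
    v = row[name]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip()
    return s or None


def _record_from_row(row: pd.Series) -> ObservationRecord:
    for col in _MANDATORY_COLUMNS:
        if _cell(row, col) is None:
            raise ValidationError(f"missing value in mandatory column {col!r}")
    try:
        setting = Setting(_cell(row, "setting"))
    except ValueError:
        raise ValidationError(f"unknown setting {_cell(row, 'setting')!r}")
    try:
        var = Variable(_cell(row, "variable"))
    except ValueError:
        raise ValidationError(f"unknown variable {_cell(row, 'variable')!r}")
    variable = VariableKey(
        var,
        Stage(_cell(row, "stage") or "none"),
        _cell(row, "method_tag") or "",
    )

    def _sal(prefix: str) -> SalinityMeasure:
        raw_value = _cell(row, f"{prefix}_salinity_value")
        unit_token = _cell(row, f"{prefix}_salinity_unit")
        unit, mult = _resolve_unit(unit_token)
        return SalinityMeasure(float(raw_value) * mult, unit)

    duration = _cell(row, "stress_duration_days")
    basis = _cell(row, "concentration_basis")
    n_geno = _cell(row, "n_genotypes")
    return ObservationRecord(
        study_id=_cell(row, "study_id"),
        experiment_id=_cell(row, "experiment_id"),
        setting=setting,
        variable=variable,
        control_salinity=_sal("control"),
        stress_salinity=_sal("stress"),
        control_value=float(_cell(row, "control_value")),
        stress_value=float(_cell(row, "stress_value")),
        stress_duration_days=float(duration) if duration is not None else None,
        concentration_basis=ConcentrationBasis(basis) if basis is not None else None,
        n_genotypes=int(float(n_geno)) if n_geno is not None else None,
        year_label=_cell(row, "year_label"),
    )


def read_corpus(
    path: str | Path, column_map: dict[str, str] | None = None
) -> tuple[list[ObservationRecord], RejectionReport]:
    """Read a corpus file into validated records plus a rejection report.

    Every input row lands either in the returned record list or in the
    report — never silently dropped.  ``column_map`` renames third-party
    columns onto the canonical schema before validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    if column_map:
        df = df.rename(columns=column_map)
    report = RejectionReport()
    if df.empty and len(df.columns) <= 1:
        report.warnings.append(f"{path}: empty corpus file")
        return [], report
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if df.empty:
        report.warnings.append(f"{path}: corpus has a header but no data rows")
        return [], report

    records: list[ObservationRecord] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            records.append(_record_from_row(row))
        except (ValidationError, ValueError) as exc:
            report.add(i, str(exc))
    n_excluded = sum(r.analysis_excluded for r in records)
    if n_excluded:
        report.warnings.append(
            f"{n_excluded} fresh-weight metabolite row(s) ingested but flagged "
            "excluded from analysis"
        )
    return records, report


def records_to_frame(records: Iterable[ObservationRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame with the canonical corpus columns."""
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "experiment_id": r.experiment_id,
                "setting": r.setting.value,
                "variable": r.variable.name.value,
                "stage": r.variable.stage.value,
                "method_tag": r.variable.method_tag or None,
                "control_salinity_value": r.control_salinity.value,
                "control_salinity_unit": r.control_salinity.unit.value,
                "stress_salinity_value": r.stress_salinity.value,
                "stress_salinity_unit": r.stress_salinity.unit.value,
                "control_value": r.control_value,
                "stress_value": r.stress_value,
                "stress_duration_days": r.stress_duration_days,
                "concentration_basis": (
                    r.concentration_basis.value if r.concentration_basis else None
                ),
                "n_genotypes": r.n_genotypes,
                "year_label": r.year_label,
            }
        )
    return pd.DataFrame(rows, columns=CORPUS_COLUMNS)


def write_corpus(records: Sequence[ObservationRecord], path: str | Path) -> None:
    """Write records as a canonical corpus file; ``read_corpus`` round-trips
    it field-for-field (absent optional fields stay absent)."""
    df = records_to_frame(records)
    if "stage" in df.columns and len(df):
        df["stage"] = df["stage"].replace({"none": None})
    df.to_csv(path, index=False)
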