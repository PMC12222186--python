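"""End-to-end orchestration: corpus -> derived effects -> bins -> tests.

This is the library face of the whole meta-analysis; the CLI is a thin
wrapper around the functions here.  A run is parameterized by a single
:class:`RunConfig`; its seed fans out to per-stage derived seeds so each
stage is independently reproducible, and every run can emit a JSON manifest
recording inputs, parameters and all filtering decisions.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    ObservationRecord,
    RejectionReport,
    Setting,
    read_corpus,
    write_corpus,
)
from .normalize import (
    RelativeObservation,
    StressAxis,
    aggregate_replicates,
    derive_all,
    filter_effective_stress,
)
from .binning import (
    HAMPEL_SIGMA_SCALE,
    BinScheme,
    BinnedGroup,
    InfeasibleBinningError,
    apply_hampel,
    assign_bins,
    bin_summary,
    build_bin_scheme,
    count_table,
    observations_table,
)
from .compare import PairwiseComparison, compare_all_pairs, comparisons_table
from .simulate import SyntheticCorpusConfig, generate_corpus

__all__ = [
    "RunConfig",
    "VariableAnalysis",
    "AnalysisResult",
    "analyze_records",
    "analyze_corpus",
    "simulate_corpus_file",
    "write_manifest",
]


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of one analysis run."""

    min_count: int = 5  # minimum points per setting per bin
    max_bins: int = 6
    hampel_k: float = 3.0
    hampel_scale: float = HAMPEL_SIGMA_SCALE  # 1.0 for the literal MAD rule
    alpha_gate: float = 0.05
    n_resamples: int = 9999
    enumeration_cap: int = 20000
    missing_anchor_policy: str = "keep"
    holm: bool = False
    seed: int = 0
    #: explicit bin edges per variable label; overrides the scheme search
    explicit_edges: dict[str, tuple[float, ...]] = field(default_factory=dict)


@dataclass
class VariableAnalysis:
    """Everything computed for one variable."""

    variable: str
    scheme: BinScheme
    groups: list[BinnedGroup]
    comparisons: list[PairwiseComparison]
    n_observations: int
    n_unassigned: int
    n_hampel_excluded: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class AnalysisResult:
    variables: dict[str, VariableAnalysis]
    derived: list[RelativeObservation]
    gate_report: list[str]
    notes: list[str]
    config: RunConfig
    counts: dict[str, int]

    def all_comparisons(self) -> list[PairwiseComparison]:
        out: list[PairwiseComparison] = []
        for va in self.variables.values():
            out.extend(va.comparisons)
        return out


def analyze_records(
    records: Sequence[ObservationRecord], config: RunConfig | None = None
) -> AnalysisResult:
    """Run the full meta-analysis pipeline on validated records.

    Stages: genotype/year aggregation -> effect derivation (dropping
    fresh-weight metabolite rows) -> effective-stress gate -> per-variable
    bin-scheme search (or the user's explicit edges) -> per-cell Hampel
    filter -> gated pairwise setting comparisons.
    """
    config = config or RunConfig()
    aggregated = aggregate_replicates(records)
    derived, notes = derive_all(aggregated)
    kept, gate_report = filter_effective_stress(
        derived, missing_anchor_policy=config.missing_anchor_policy
    )
    counts = {
        "records_in": len(records),
        "after_aggregation": len(aggregated),
        "derived": len(derived),
        "after_effective_stress_gate": len(kept),
    }

    variables: dict[str, VariableAnalysis] = {}
    labels = sorted({o.variable.label() for o in kept})
    for label in labels:
        table = observations_table(kept, label)
        if table.empty:
            continue
        warnings: list[str] = []
        try:
            if label in config.explicit_edges:
                covered = frozenset(Setting(s) for s in table["setting"].unique())
                scheme = BinScheme(
                    label,
                    StressAxis(table["stress_axis"].iloc[0]),
                    tuple(float(e) for e in config.explicit_edges[label]),
                    covered,
                    config.min_count,
                )
            else:
                scheme, warnings = build_bin_scheme(
                    table, min_count=config.min_count, max_bins=config.max_bins
                )
        except InfeasibleBinningError as exc:
            variables[label] = VariableAnalysis(
                label,
                scheme=None,  # type: ignore[arg-type]
                groups=[],
                comparisons=[],
                n_observations=len(table),
                n_unassigned=len(table),
                n_hampel_excluded=0,
                warnings=[str(exc)],
            )
            continue
        covered_table = table[table["setting"].isin(scheme.settings_covered)]
        groups, unassigned = assign_bins(covered_table, scheme)
        filtered = apply_hampel(
            groups, k=config.hampel_k, scale=config.hampel_scale
        )
        comparisons = compare_all_pairs(
            filtered,
            label,
            seed=config.seed,
            alpha_gate=config.alpha_gate,
            n_resamples=config.n_resamples,
            enumeration_cap=config.enumeration_cap,
            holm=config.holm,
        )
        variables[label] = VariableAnalysis(
            label,
            scheme=scheme,
            groups=filtered,
            comparisons=comparisons,
            n_observations=len(table),
            n_unassigned=len(unassigned)
            + (len(table) - len(covered_table)),
            n_hampel_excluded=sum(len(g.excluded) for g in filtered),
            warnings=warnings,
        )
    return AnalysisResult(
        variables=variables,
        derived=kept,
        gate_report=gate_report,
        notes=notes,
        config=config,
        counts=counts,
    )


def write_manifest(path: Path, payload: dict) -> None:
    payload = dict(payload)
    payload["saltmeta_version"] = __version__
    payload["python_version"] = platform.python_version()
    payload["numpy_version"] = np.__version__
    payload["pandas_version"] = pd.__version__
    path.write_text(json.dumps(payload, indent=2, default=str), encoding="utf-8")


def analyze_corpus(
    corpus_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    column_map: dict[str, str] | None = None,
) -> AnalysisResult:
    """Read a corpus file, run the pipeline, and write all output tables
    plus a machine-readable run manifest into ``out_dir``."""
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, report = read_corpus(corpus_path, column_map=column_map)
    if not records:
        raise ValueError(f"no analyzable records in {corpus_path}")
    result = analyze_records(records, config)

    from .normalize import write_derived

    write_derived(result.derived, out / "derived.csv")
    comparisons_table(result.all_comparisons()).to_csv(
        out / "comparisons.csv", index=False
    )
    for label, va in result.variables.items():
        safe = label.replace(":", "_").replace("/", "_")
        if va.scheme is None:
            continue
        count_table(va.groups).to_csv(out / f"bin_counts_{safe}.csv")
        bin_summary(va.groups).to_csv(out / f"bin_summary_{safe}.csv", index=False)

    manifest = {
        "command": "analyze",
        "input": str(corpus_path),
        "config": asdict(config),
        "seed": config.seed,
        "n_rejected_rows": len(report),
        "rejections": [(r.row, r.reason) for r in report.rejections],
        "read_warnings": report.warnings,
        "counts": result.counts,
        "effective_stress_gate": result.gate_report,
        "per_variable": {
            label: {
                "edges": list(va.scheme.edges) if va.scheme else None,
                "settings_covered": (
                    sorted(s.value for s in va.scheme.settings_covered)
                    if va.scheme
                    else []
                ),
                "n_observations": va.n_observations,
                "n_unassigned": va.n_unassigned,
                "n_hampel_excluded": va.n_hampel_excluded,
                "warnings": va.warnings,
            }
            for label, va in result.variables.items()
        },
    }
    write_manifest(out / "manifest.json", manifest)
    return result


def simulate_corpus_file(
    config: SyntheticCorpusConfig, out_path: str | Path
) -> list[ObservationRecord]:
    """Generate a synthetic corpus and write it in the corpus dialect, with
    a manifest alongside."""
    records = generate_corpus(config)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    write_corpus(records, out_path)
    manifest = {
        "command": "simulate",
        "seed": config.seed,
        "n_records": len(records),
        "studies_per_setting": {
            s.value: n for s, n in config.studies_per_setting.items()
        },
        "params": {
            s.value: asdict(p) for s, p in config.params.items()
        },
        "ec_range": list(config.ec_range),
        "duration_range": list(config.duration_range),
        "variables": [v.label() for v in config.variables],
    }
    write_manifest(out_path.with_suffix(".manifest.json"), manifest)
    return records
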