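"""Stress-axis binning and robust per-bin outlier filtering.

To compare settings along a dose-response curve, observations are grouped
into bins of the stress axis (relative EC or stress integral).  A usable bin
scheme must leave at least ``min_count`` points per covered setting in every
bin, and its bins should be *comparable*: within a bin, the mean stress level
should be as similar as possible across settings, otherwise a between-setting
difference could just reflect a different dose mix.  The scheme search below
formalizes that as minimizing, over a candidate set of edge sequences, the
worst-bin spread of per-setting mean axis values.

Within each bin x setting cell a single-pass Hampel filter excludes points
farther than ``k`` (scaled) median absolute deviations from the cell median.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import Setting
from .normalize import RelativeObservation, StressAxis

__all__ = [
    "HAMPEL_SIGMA_SCALE",
    "hampel_mask",
    "hampel_filter",
    "BinScheme",
    "BinnedGroup",
    "InfeasibleBinningError",
    "AxisMismatchError",
    "observations_table",
    "build_bin_scheme",
    "assign_bins",
    "apply_hampel",
    "count_table",
    "bin_summary",
    "scheme_to_yaml",
    "scheme_from_yaml",
]

#: Consistency factor making the MAD an unbiased estimate of the Gaussian
#: standard deviation; the Hampel-filter convention.
HAMPEL_SIGMA_SCALE = 1.4826


class InfeasibleBinningError(ValueError):
    """No bin scheme can satisfy the per-setting count constraint."""


class AxisMismatchError(ValueError):
    """A scheme built for one stress axis was applied to another."""


def hampel_mask(
    values: Sequence[float], k: float = 3.0, scale: float = HAMPEL_SIGMA_SCALE
) -> np.ndarray:
    """Boolean retain-mask of the single-pass Hampel filter.

    A value is excluded when ``|v - median| > k * scale * MAD`` where the
    median and the MAD (median absolute deviation) are computed once on the
    full input — the filter is not iterated.  With ``scale = 1.4826`` the
    threshold is ``k`` robust standard deviations; ``scale = 1.0`` gives the
    literal "k median absolute deviations" reading.  A zero MAD (at least
    half the values identical) excludes nothing: the literal rule would
    otherwise flag every non-median point.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("hampel filter needs at least one value")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return np.ones(v.shape, dtype=bool)
    return np.abs(v - med) <= k * scale * mad


def hampel_filter(
    values: Sequence[float], k: float = 3.0, scale: float = HAMPEL_SIGMA_SCALE
) -> tuple[list[float], list[float]]:
    """Split values into (retained, excluded) by the Hampel rule."""
    v = np.asarray(values, dtype=float)
    keep = hampel_mask(v, k=k, scale=scale)
    return v[keep].tolist(), v[~keep].tolist()


@dataclass(frozen=True)
class BinScheme:
    """A partition of the stress axis for one variable.

    Bins are half-open ``[e_i, e_{i+1})`` with the last bin closed at the
    top.  A degenerate scheme with two equal edges represents a single bin
    holding one repeated axis value.
    """

    variable: str
    stress_axis: StressAxis
    edges: tuple[float, ...]
    settings_covered: frozenset[Setting]
    min_count: int = 5

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) < 2:
            raise ValueError("a bin scheme needs at least two edges")
        degenerate = len(e) == 2 and e[0] == e[1]
        if not degenerate and any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError(f"edges must be strictly increasing, got {e}")

    @property
    def n_bins(self) -> int:
        return max(1, len(self.edges) - 1)

    def bin_of(self, x: np.ndarray) -> np.ndarray:
        """Bin index per value; -1 marks out-of-range values."""
        x = np.asarray(x, dtype=float)
        e = np.asarray(self.edges, dtype=float)
        if e[0] == e[-1]:  # degenerate single-value scheme
            return np.where(x == e[0], 0, -1)
        idx = np.searchsorted(e, x, side="right") - 1
        idx = np.where(x == e[-1], len(e) - 2, idx)  # last bin closed
        out = (x < e[0]) | (x > e[-1])
        return np.where(out, -1, idx)


@dataclass
class BinnedGroup:
    """Retained and excluded response ratios of one bin x setting cell."""

    bin_index: int
    setting: Setting
    values: np.ndarray
    axis_values: np.ndarray
    excluded: list[tuple[float, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean_axis(self) -> float:
        return float(np.mean(self.axis_values)) if self.axis_values.size else np.nan

    @property
    def mean_response(self) -> float:
        return float(np.mean(self.values)) if self.values.size else np.nan

    @property
    def se_response(self) -> float:
        if self.values.size < 2:
            return np.nan
        return float(np.std(self.values, ddof=1) / np.sqrt(self.values.size))


def observations_table(
    observations: Iterable[RelativeObservation],
    variable: str | None = None,
) -> pd.DataFrame:
    """Long table (setting, axis, response) for binning, one variable at a
    time; observations lacking an axis value (integral axis without a
    recorded duration) are dropped here."""
    rows = []
    for o in observations:
        if variable is not None and o.variable.label() != variable:
            continue
        ax = o.axis_value
        if ax is None:
            continue
        rows.append(
            {
                "variable": o.variable.label(),
                "stress_axis": o.stress_axis.value,
                "setting": o.setting,
                "axis": ax,
                "response": o.relative_response,
            }
        )
    return pd.DataFrame(
        rows, columns=["variable", "stress_axis", "setting", "axis", "response"]
    )


def _cells_feasible(
    table: pd.DataFrame, edges: np.ndarray, settings: Sequence[Setting], min_count: int
) -> bool:
    scheme_bins = np.searchsorted(edges, table["axis"].to_numpy(), side="right") - 1
    scheme_bins = np.where(
        table["axis"].to_numpy() == edges[-1], len(edges) - 2, scheme_bins
    )
    for b in range(len(edges) - 1):
        for s in settings:
            n = int(np.sum((scheme_bins == b) & (table["setting"] == s).to_numpy()))
            if n < min_count:
                return False
    return True


def _spread_objective(
    table: pd.DataFrame, edges: np.ndarray, settings: Sequence[Setting]
) -> float:
    """J = worst-bin spread of per-setting mean axis values."""
    axis = table["axis"].to_numpy()
    bins = np.searchsorted(edges, axis, side="right") - 1
    bins = np.where(axis == edges[-1], len(edges) - 2, bins)
    worst = 0.0
    for b in range(len(edges) - 1):
        means = []
        for s in settings:
            sel = (bins == b) & (table["setting"] == s).to_numpy()
            if sel.any():
                means.append(float(axis[sel].mean()))
        if len(means) >= 2:
            worst = max(worst, max(means) - min(means))
    return worst


def _candidate_edges(
    pooled: np.ndarray, n_bins: int
) -> list[np.ndarray]:
    """Quantile-seeded and equal-width edge sequences for a bin count."""
    lo, hi = float(pooled.min()), float(pooled.max())
    cands = []
    qs = np.linspace(0, 1, n_bins + 1)
    qe = np.unique(np.quantile(pooled, qs))
    if len(qe) == n_bins + 1:
        qe[0], qe[-1] = lo, hi
        cands.append(qe)
    we = np.linspace(lo, hi, n_bins + 1)
    if len(np.unique(we)) == n_bins + 1:
        cands.append(we)
    return cands


def _greedy_merge(
    table: pd.DataFrame,
    edges: np.ndarray,
    settings: Sequence[Setting],
    min_count: int,
) -> np.ndarray | None:
    """Merge adjacent bins until every cell meets min_count; None if the
    constraint cannot be met even as a single bin."""
    edges = edges.copy()
    while len(edges) > 2:
        if _cells_feasible(table, edges, settings, min_count):
            return edges
        # find the first deficient bin and merge it with its smaller neighbour
        axis = table["axis"].to_numpy()
        bins = np.searchsorted(edges, axis, side="right") - 1
        bins = np.where(axis == edges[-1], len(edges) - 2, bins)
        deficient = None
        for b in range(len(edges) - 1):
            for s in settings:
                if np.sum((bins == b) & (table["setting"] == s).to_numpy()) < min_count:
                    deficient = b
                    break
            if deficient is not None:
                break
        counts = np.array([np.sum(bins == b) for b in range(len(edges) - 1)])
        if deficient == 0:
            drop = 1
        elif deficient == len(edges) - 2:
            drop = len(edges) - 2
        else:
            # merge toward the neighbour with fewer points; tie goes left
            drop = (
                deficient
                if counts[deficient - 1] <= counts[deficient + 1]
                else deficient + 1
            )
        edges = np.delete(edges, drop)
    if _cells_feasible(table, edges, settings, min_count):
        return edges
    return None


def build_bin_scheme(
    table: pd.DataFrame,
    min_count: int = 5,
    max_bins: int = 6,
) -> tuple[BinScheme, list[str]]:
    """Search for the most comparable feasible bin scheme.

    Candidate edge sequences (quantile-seeded and equal-width, each greedily
    merged until feasible) are ranked by bin count first — the point of
    binning is to resolve the dose-response, so the finest feasible
    partition wins — and within a bin count by the comparability objective
    ``J``, the worst-bin spread of per-setting mean axis values; remaining
    ties go to lexicographically smaller edges.  Settings that cannot reach
    ``min_count`` points in any
    single bin spanning the whole range are dropped from coverage with a
    warning; fewer than two coverable settings is an error.  The search is
    deterministic given its inputs.
    """
    if table.empty:
        raise InfeasibleBinningError("no observations to bin")
    variable = str(table["variable"].iloc[0])
    axis_name = StressAxis(table["stress_axis"].iloc[0])
    warnings: list[str] = []

    counts = table.groupby("setting", observed=True)["axis"].count()
    covered = [Setting(s) for s, n in counts.items() if n >= min_count]
    dropped = [Setting(s) for s, n in counts.items() if n < min_count]
    for s in dropped:
        warnings.append(
            f"setting {s.value} has only {int(counts[s])} point(s) "
            f"(< min_count={min_count}); dropped from coverage"
        )
    if len(covered) < 2:
        raise InfeasibleBinningError(
            f"fewer than 2 settings reach min_count={min_count} for {variable}"
        )
    sub = table[table["setting"].isin(covered)]
    pooled = np.sort(sub["axis"].to_numpy(dtype=float))

    if pooled[0] == pooled[-1]:  # all points share one axis value
        scheme = BinScheme(
            variable, axis_name, (pooled[0], pooled[0]), frozenset(covered), min_count
        )
        return scheme, warnings

    candidates: list[np.ndarray] = []
    for n_bins in range(1, max_bins + 1):
        for seed_edges in _candidate_edges(pooled, n_bins):
            merged = _greedy_merge(sub, seed_edges, covered, min_count)
            if merged is not None:
                candidates.append(merged)
    if not candidates:
        raise InfeasibleBinningError(
            f"no feasible bin scheme for {variable} at min_count={min_count}"
        )
    # dedupe, then rank by (-n_bins, J, edges)
    uniq: dict[tuple[float, ...], np.ndarray] = {}
    for e in candidates:
        uniq[tuple(np.round(e, 12))] = e
    ranked = sorted(
        uniq.values(),
        key=lambda e: (
            -(len(e) - 1),
            round(_spread_objective(sub, e, covered), 12),
            tuple(e),
        ),
    )
    best = ranked[0]
    scheme = BinScheme(
        variable, axis_name, tuple(float(x) for x in best), frozenset(covered), min_count
    )
    return scheme, warnings


def assign_bins(
    table: pd.DataFrame, scheme: BinScheme
) -> tuple[list[BinnedGroup], pd.DataFrame]:
    """Assign observations to the scheme's bins.

    Returns one :class:`BinnedGroup` per non-empty bin x covered-setting cell
    plus a table of out-of-range (unassigned) observations.  A value on an
    interior edge belongs to the upper bin; a value on the last edge belongs
    to the last bin.
    """
    if table.empty:
        return [], table.copy()
    axes = set(table["stress_axis"].unique())
    if axes != {scheme.stress_axis.value}:
        raise AxisMismatchError(
            f"scheme is on axis {scheme.stress_axis.value!r} but observations "
            f"use {sorted(axes)}"
        )
    x = table["axis"].to_numpy(dtype=float)
    idx = scheme.bin_of(x)
    unassigned = table[idx == -1].copy()
    groups: list[BinnedGroup] = []
    for b in range(scheme.n_bins):
        for s in sorted(scheme.settings_covered, key=lambda s: s.value):
            sel = (idx == b) & (table["setting"] == s).to_numpy()
            if not sel.any():
                continue
            groups.append(
                BinnedGroup(
                    bin_index=b,
                    setting=s,
                    values=table["response"].to_numpy(dtype=float)[sel],
                    axis_values=x[sel],
                )
            )
    return groups, unassigned


def apply_hampel(
    groups: Sequence[BinnedGroup],
    k: float = 3.0,
    scale: float = HAMPEL_SIGMA_SCALE,
) -> list[BinnedGroup]:
    """Hampel-filter every bin x setting cell; excluded points are kept on
    the group with the reason recorded."""
    out: list[BinnedGroup] = []
    for g in groups:
        keep = hampel_mask(g.values, k=k, scale=scale)
        excluded = [
            (float(v), f"hampel k={k:g} scale={scale:g}")
            for v in g.values[~keep]
        ]
        out.append(
            BinnedGroup(
                bin_index=g.bin_index,
                setting=g.setting,
                values=g.values[keep],
                axis_values=g.axis_values[keep],
                excluded=excluded,
            )
        )
    return out


def count_table(groups: Sequence[BinnedGroup]) -> pd.DataFrame:
    """Per-bin per-setting retained counts, mirroring the in-figure count
    tables of the dose-response plots."""
    rows = [
        {"bin": g.bin_index, "setting": g.setting.value, "n": g.n} for g in groups
    ]
    df = pd.DataFrame(rows, columns=["bin", "setting", "n"])
    if df.empty:
        return df
    return df.pivot_table(
        index="setting", columns="bin", values="n", fill_value=0, aggfunc="sum"
    )


def bin_summary(groups: Sequence[BinnedGroup]) -> pd.DataFrame:
    """Binned means +/- SE per setting (the numbers behind a dose-response
    figure)."""
    rows = []
    for g in groups:
        rows.append(
            {
                "bin": g.bin_index,
                "setting": g.setting.value,
                "n": g.n,
                "n_excluded": len(g.excluded),
                "mean_axis": g.mean_axis,
                "mean_response": g.mean_response,
                "se_response": g.se_response,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bin",
            "setting",
            "n",
            "n_excluded",
            "mean_axis",
            "mean_response",
            "se_response",
        ],
    )


def scheme_to_yaml(scheme: BinScheme, path: str | Path) -> None:
    payload = {
        "variable": scheme.variable,
        "stress_axis": scheme.stress_axis.value,
        "edges": [float(e) for e in scheme.edges],
        "min_count": scheme.min_count,
        "settings_covered": sorted(s.value for s in scheme.settings_covered),
    }
    Path(path).write_text(yaml.safe_dump(payload), encoding="utf-8")


def scheme_from_yaml(path: str | Path) -> BinScheme:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return BinScheme(
        variable=payload["variable"],
        stress_axis=StressAxis(payload["stress_axis"]),
        edges=tuple(float(e) for e in payload["edges"]),
        settings_covered=frozenset(
            Setting(s) for s in payload["settings_covered"]
        ),
        min_count=int(payload.get("min_count", 5)),
    )
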