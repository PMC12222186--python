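"""Pairwise comparison of experimental settings over overlapping bins.

For each pair of settings sharing at least one bin, the retained response
ratios are pooled across the overlapping bins and a two-sample test is run.
Which test runs is decided by a gate: if the two samples look normal
(Shapiro-Wilk per group, on the raw or the log scale) *and* pass a variance
homogeneity check (Brown-Forsythe by default), a permutation t-test is used
on that scale; otherwise a Mann-Whitney U test.  Both tests are implemented
here from first principles — the permutation null is enumerated exhaustively
when the label-assignment count is small enough, otherwise Monte-Carlo
sampled with an add-one p-value so a sampled p is never zero.
"""

from __future__ import annotations

import enum
import itertools
import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Setting
from .binning import BinnedGroup

__all__ = [
    "Transform",
    "TestKind",
    "GateRecord",
    "TestSelection",
    "PermutationTResult",
    "MannWhitneyResult",
    "PairwiseComparison",
    "select_test",
    "permutation_t_test",
    "mann_whitney_u",
    "compare_all_pairs",
    "comparisons_table",
    "pair_seed",
]


class Transform(str, enum.Enum):
    RAW = "raw"
    LOG = "log"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TestKind(str, enum.Enum):
    PERMUTATION_T = "permutation_t"
    MANN_WHITNEY = "mann_whitney"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GateRecord:
    """p-values of the gate tests actually run (None when skipped)."""

    shapiro_raw_p: tuple[float, float] | None = None
    shapiro_log_p: tuple[float, float] | None = None
    variance_hom_p: float | None = None


@dataclass(frozen=True)
class TestSelection:
    test: TestKind
    transform: Transform
    gates: GateRecord
    note: str = ""


def _shapiro_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    out = []
    for g in (a, b):
        if np.ptp(g) == 0:  # constant sample: normality is ill-posed, fail it
            out.append(0.0)
            continue
        out.append(float(stats.shapiro(g).pvalue))
    return (out[0], out[1])


def select_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alpha_gate: float = 0.05,
    variance_test: str = "brown-forsythe",
) -> TestSelection:
    """Decide which two-sample test to run, and on which scale.

    Decision tree: Shapiro-Wilk on each raw sample; if both pass
    (p > ``alpha_gate``) the candidate scale is raw, otherwise Shapiro-Wilk
    on the log-transformed samples (only if all values are positive); if
    both pass there, the candidate scale is log.  With a normal candidate
    scale in hand, variance homogeneity is tested on that scale: a pass
    selects the permutation t-test, any failure falls back to the
    Mann-Whitney U test on the raw data.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if min(a.size, b.size) < 3:
        return TestSelection(
            TestKind.MANN_WHITNEY,
            Transform.RAW,
            GateRecord(),
            note="sample too small for the normality gate",
        )
    raw_p = _shapiro_pair(a, b)
    log_p: tuple[float, float] | None = None
    candidate: Transform | None = None
    if min(raw_p) > alpha_gate:
        candidate = Transform.RAW
    elif a.min() > 0 and b.min() > 0:
        log_p = _shapiro_pair(np.log(a), np.log(b))
        if min(log_p) > alpha_gate:
            candidate = Transform.LOG
    note = ""
    if candidate is None and (a.min() <= 0 or b.min() <= 0) and min(raw_p) <= alpha_gate:
        note = "log branch skipped (non-positive values)"
    var_p: float | None = None
    if candidate is not None:
        ta, tb = (np.log(a), np.log(b)) if candidate is Transform.LOG else (a, b)
        center = "median" if variance_test == "brown-forsythe" else "mean"
        var_p = float(stats.levene(ta, tb, center=center).pvalue)
        if var_p > alpha_gate:
            return TestSelection(
                TestKind.PERMUTATION_T,
                candidate,
                GateRecord(raw_p, log_p, var_p),
            )
        note = "variance homogeneity failed"
    return TestSelection(
        TestKind.MANN_WHITNEY,
        Transform.RAW,
        GateRecord(raw_p, log_p, var_p),
        note=note or "normality failed on raw and log scales",
    )


@dataclass(frozen=True)
class PermutationTResult:
    statistic: float
    p_value: float
    n_permutations: int | str  # number sampled, or "exact"


def _pooled_t(sum_a, sumsq_a, n_a, total, totalsq, n):
    """Pooled-variance Student t from sufficient statistics of group A."""
    n_b = n - n_a
    sum_b = total - sum_a
    sumsq_b = totalsq - sumsq_a
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    ss_a = sumsq_a - n_a * mean_a**2
    ss_b = sumsq_b - n_b * mean_b**2
    sp2 = (ss_a + ss_b) / (n - 2)
    sp2 = np.maximum(sp2, 0.0)
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            denom > 0,
            diff / np.where(denom > 0, denom, 1.0),
            np.where(diff == 0, 0.0, np.inf * np.sign(diff)),
        )
    return t


def permutation_t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    n_resamples: int = 9999,
    seed: int | np.random.Generator | None = None,
    enumeration_cap: int = 20000,
) -> PermutationTResult:
    """Two-sided two-sample permutation test on the pooled-variance t.

    The null distribution is the t statistic over relabelings of group
    membership.  When the number of distinct label assignments
    ``C(n_a+n_b, n_a)`` is at most ``enumeration_cap`` the null is
    enumerated exhaustively and the p-value is the exact fraction of
    assignments with ``|t*| >= |t_obs|``; otherwise ``n_resamples`` random
    relabelings are drawn and ``p = (1 + #{|t*| >= |t_obs|}) / (1 + B)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValueError("permutation t-test needs at least 2 values per group")
    pooled = np.concatenate([a, b])
    n = n_a + n_b
    total, totalsq = pooled.sum(), (pooled**2).sum()
    t_obs = float(
        _pooled_t(a.sum(), (a**2).sum(), n_a, total, totalsq, n)
    )
    if np.ptp(pooled) == 0:  # no variation anywhere: nothing to test
        return PermutationTResult(0.0, 1.0, "exact")
    tol = 1e-12 * max(1.0, abs(t_obs) if math.isfinite(t_obs) else 1.0)
    thresh = abs(t_obs) - tol if math.isfinite(t_obs) else np.inf

    n_assignments = math.comb(n, n_a)
    if n_assignments <= enumeration_cap:
        count = 0
        for idx in itertools.combinations(range(n), n_a):
            sel = pooled[list(idx)]
            t_star = float(
                _pooled_t(sel.sum(), (sel**2).sum(), n_a, total, totalsq, n)
            )
            if (math.isfinite(t_obs) and abs(t_star) >= thresh) or (
                not math.isfinite(t_obs) and not math.isfinite(t_star)
            ):
                count += 1
        return PermutationTResult(t_obs, count / n_assignments, "exact")

    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    # chunked so the permutation matrix never gets large
    chunk = max(1, min(n_resamples, int(2e6) // n))
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        order = np.argsort(rng.random((m, n)), axis=1)
        perm = pooled[order]
        grp_a = perm[:, :n_a]
        t_star = _pooled_t(
            grp_a.sum(axis=1), (grp_a**2).sum(axis=1), n_a, total, totalsq, n
        )
        if math.isfinite(t_obs):
            count += int(np.sum(np.abs(t_star) >= thresh))
        else:
            count += int(np.sum(~np.isfinite(t_star)))
        done += m
    return PermutationTResult(
        t_obs, (1 + count) / (1 + n_resamples), n_resamples
    )


@dataclass(frozen=True)
class MannWhitneyResult:
    statistic: float  # U of the first sample
    p_value: float
    method: str  # "exact" or "normal"


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    enumeration_cap: int = 20000,
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``U = #{(i, j): a_i > b_j} + 0.5 #{ties}``.  For tie-free data with at
    most ``enumeration_cap`` rank splits the p-value is exact — the fraction
    of splits whose U deviates from the null mean ``n_a n_b / 2`` at least
    as much as observed.  Otherwise a normal approximation with mid-rank tie
    correction and continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 1 or n_b < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[:n_a].sum()
    u = float(r_a - n_a * (n_a + 1) / 2.0)
    mu = n_a * n_b / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    n = n_a + n_b
    if not has_ties and math.comb(n, n_a) <= enumeration_cap:
        dev = abs(u - mu)
        all_ranks = np.arange(1, n + 1)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), n_a):
            u_star = all_ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0
            total += 1
            if abs(u_star - mu) >= dev - 1e-12:
                count += 1
        return MannWhitneyResult(u, count / total, "exact")

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # every value tied
        return MannWhitneyResult(u, 1.0, "normal")
    dev = abs(u - mu)
    z = max(0.0, dev - 0.5) / math.sqrt(var)  # continuity correction
    p = min(1.0, max(2.0 * float(stats.norm.sf(z)), 5e-324))  # keep p in (0, 1]
    return MannWhitneyResult(u, p, "normal")


@dataclass(frozen=True)
class PairwiseComparison:
    """Outcome of one setting-vs-setting comparison for one variable."""

    variable: str
    pair: tuple[Setting, Setting]
    bins_used: tuple[int, ...]
    n_a: int
    n_b: int
    gates: GateRecord
    transform: Transform | None
    test_used: TestKind | None
    statistic: float | None
    p_value: float | None
    n_permutations: int | str | None
    testable: bool = True
    note: str = ""


def pair_seed(base_seed: int, variable: str, s_a: Setting, s_b: Setting) -> int:
    """Stable per-comparison seed below 2**31, derived from the run seed and
    the comparison's identity so every pair is independently reproducible."""
    tag = f"{variable}|{s_a.value}|{s_b.value}"
    return (int(base_seed) ^ zlib.crc32(tag.encode())) % (2**31 - 1)


def compare_all_pairs(
    groups: Sequence[BinnedGroup],
    variable: str,
    seed: int = 0,
    alpha_gate: float = 0.05,
    n_resamples: int = 9999,
    enumeration_cap: int = 20000,
    holm: bool = False,
) -> list[PairwiseComparison]:
    """Run the gated comparison for every unordered pair of settings.

    For a pair, the *overlapping bins* are those where both settings retain
    at least one filtered value; the retained values are pooled across those
    bins, the gate picks the test, and the chosen test is run.  Pairs with
    no overlapping bin are reported as untestable.  No multiplicity
    correction is applied by default; ``holm=True`` adds a Holm adjustment
    across the pairs of this variable.
    """
    by_setting: dict[Setting, dict[int, BinnedGroup]] = {}
    for g in groups:
        if g.n > 0:
            by_setting.setdefault(g.setting, {})[g.bin_index] = g
    settings = sorted(by_setting, key=lambda s: s.value)
    results: list[PairwiseComparison] = []
    for s_a, s_b in itertools.combinations(settings, 2):
        overlap = sorted(set(by_setting[s_a]) & set(by_setting[s_b]))
        if not overlap:
            results.append(
                PairwiseComparison(
                    variable, (s_a, s_b), (), 0, 0, GateRecord(),
                    None, None, None, None, None,
                    testable=False, note="no overlapping bins",
                )
            )
            continue
        a = np.concatenate([by_setting[s_a][b].values for b in overlap])
        b = np.concatenate([by_setting[s_b][b].values for b in overlap])
        sel = select_test(a, b, alpha_gate=alpha_gate)
        if sel.test is TestKind.PERMUTATION_T:
            ta = np.log(a) if sel.transform is Transform.LOG else a
            tb = np.log(b) if sel.transform is Transform.LOG else b
            res = permutation_t_test(
                ta,
                tb,
                n_resamples=n_resamples,
                seed=pair_seed(seed, variable, s_a, s_b),
                enumeration_cap=enumeration_cap,
            )
            stat, p, n_perm = res.statistic, res.p_value, res.n_permutations
        else:
            mw = mann_whitney_u(a, b, enumeration_cap=enumeration_cap)
            stat, p, n_perm = mw.statistic, mw.p_value, None
        results.append(
            PairwiseComparison(
                variable, (s_a, s_b), tuple(overlap), int(a.size), int(b.size),
                sel.gates, sel.transform, sel.test, float(stat), float(p),
                n_perm, testable=True, note=sel.note,
            )
        )
    if holm:
        results = _holm_adjust(results)
    return results


def _holm_adjust(results: list[PairwiseComparison]) -> list[PairwiseComparison]:
    from dataclasses import replace as _replace

    testable = [r for r in results if r.testable and r.p_value is not None]
    m = len(testable)
    order = sorted(range(m), key=lambda i: testable[i].p_value)
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * testable[i].p_value)
        adj[i] = min(1.0, running)
    out = []
    j = 0
    for r in results:
        if r.testable and r.p_value is not None:
            out.append(_replace(r, p_value=adj[j]))
            j += 1
        else:
            out.append(r)
    return out


def comparisons_table(results: Iterable[PairwiseComparison]) -> pd.DataFrame:
    """Flat results table (variable, pair, n, gates, transform, test,
    statistic, p)."""
    rows = []
    for r in results:
        rows.append(
            {
                "variable": r.variable,
                "setting_a": r.pair[0].value,
                "setting_b": r.pair[1].value,
                "bins_used": ";".join(map(str, r.bins_used)),
                "n_a": r.n_a,
                "n_b": r.n_b,
                "shapiro_raw_p": (
                    min(r.gates.shapiro_raw_p) if r.gates.shapiro_raw_p else None
                ),
                "shapiro_log_p": (
                    min(r.gates.shapiro_log_p) if r.gates.shapiro_log_p else None
                ),
                "variance_hom_p": r.gates.variance_hom_p,
                "transform": r.transform.value if r.transform else None,
                "test": r.test_used.value if r.test_used else None,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "n_permutations": r.n_permutations,
                "testable": r.testable,
                "note": r.note,
            }
        )
    return pd.DataFrame(rows)
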