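"""Hampel filter against its set-builder definition; bin scheme search and
assignment conventions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltmeta.binning import (
    BinScheme,
    InfeasibleBinningError,
    AxisMismatchError,
    apply_hampel,
    assign_bins,
    bin_summary,
    build_bin_scheme,
    count_table,
    hampel_filter,
    hampel_mask,
    scheme_from_yaml,
    scheme_to_yaml,
)
from saltmeta.io import Setting
from saltmeta.normalize import StressAxis
from conftest import brute_force_hampel


def _table(settings, axes, responses, variable="grain_yield", axis="relative_ec"):
    return pd.DataFrame(
        {
            "variable": variable,
            "stress_axis": axis,
            "setting": [Setting(s) for s in settings],
            "axis": np.asarray(axes, dtype=float),
            "response": np.asarray(responses, dtype=float),
        }
    )


class TestHampel:
    def test_worked_example(self):
        retained, excluded = hampel_filter([1, 2, 3, 4, 100], k=3, scale=1.4826)
        # median 3, MAD 1, threshold 3*1.4826 = 4.4478
        assert retained == [1, 2, 3, 4]
        assert excluded == [100]

    def test_all_equal_mad_zero_excludes_nothing(self):
        retained, excluded = hampel_filter([7, 7, 7, 7])
        assert retained == [7, 7, 7, 7] and excluded == []

    def test_singleton_retained(self):
        assert hampel_filter([5]) == ([5], [])

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            hampel_filter([])

    @given(
        values=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=12
        ),
        k=st.sampled_from([1.0, 2.0, 3.0]),
        scale=st.sampled_from([1.0, 1.4826]),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_definition(self, values, k, scale):
        retained, excluded = hampel_filter(values, k=k, scale=scale)
        bf_ret, bf_exc = brute_force_hampel(values, k=k, scale=scale)
        assert sorted(retained) == sorted(bf_ret)
        assert sorted(excluded) == sorted(bf_exc)

    @given(
        values=st.lists(st.integers(-1000, 1000), min_size=2, max_size=12),
        a=st.integers(-20, 20).filter(lambda x: x != 0),
        b=st.integers(-500, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_affine_invariance(self, values, a, b):
        base = hampel_mask([float(v) for v in values])
        transformed = hampel_mask([float(a * v + b) for v in values])
        assert np.array_equal(base, transformed)

    def test_order_invariance(self, rng):
        values = rng.normal(size=11).tolist() + [40.0]
        perm = rng.permutation(values)
        assert sorted(hampel_filter(values)[1]) == sorted(
            hampel_filter(perm)[1]
        )


class TestAssignment:
    scheme = BinScheme(
        "grain_yield",
        StressAxis.RELATIVE_EC,
        (0.0, 10.0, 20.0),
        frozenset({Setting.FIELD, Setting.GREENHOUSE}),
    )

    def test_interior_edge_goes_to_upper_bin(self):
        assert self.scheme.bin_of([10.0])[0] == 1

    def test_last_edge_belongs_to_last_bin(self):
        assert self.scheme.bin_of([20.0])[0] == 1

    def test_out_of_range_reported_unassigned(self):
        t = _table(["field"] * 3, [-1.0, 5.0, 25.0], [1, 1, 1])
        groups, unassigned = assign_bins(t, self.scheme)
        assert len(unassigned) == 2
        assert sum(g.n for g in groups) == 1

    def test_partition_conserves_totals(self, rng):
        n = 200
        t = _table(
            rng.choice(["field", "greenhouse"], n),
            rng.uniform(0, 20, n),
            rng.uniform(0, 1, n),
        )
        groups, unassigned = assign_bins(t, self.scheme)
        assert sum(g.n for g in groups) + len(unassigned) == n
        # each point in exactly one bin: reconstruct and compare multisets
        got = np.sort(np.concatenate([g.axis_values for g in groups]))
        exp = np.sort(t["axis"][self.scheme.bin_of(t["axis"].to_numpy()) >= 0])
        assert np.allclose(got, exp)

    def test_axis_mismatch_rejected(self):
        t = _table(["field"], [5.0], [1.0], axis="stress_integral")
        with pytest.raises(AxisMismatchError):
            assign_bins(t, self.scheme)


class TestSchemeSearch:
    def test_feasible_scheme_on_uniform_data(self, rng):
        settings_ = ["field", "greenhouse", "outdoor_pots"] * 20
        t = _table(settings_, rng.uniform(0, 30, 60), rng.uniform(0, 1, 60))
        scheme, warnings = build_bin_scheme(t, min_count=5)
        assert warnings == []
        assert scheme.n_bins >= 2
        # exhaustive check: every covered cell holds >= 5 points
        groups, _ = assign_bins(t, scheme)
        per_cell = {}
        for g in groups:
            per_cell[(g.bin_index, g.setting)] = g.n
        for b in range(scheme.n_bins):
            for s in scheme.settings_covered:
                assert per_cell.get((b, s), 0) >= 5

    def test_setting_below_min_count_dropped(self, rng):
        settings_ = ["field"] * 20 + ["greenhouse"] * 20 + ["climate_chamber"] * 4
        t = _table(settings_, rng.uniform(0, 30, 44), rng.uniform(0, 1, 44))
        scheme, warnings = build_bin_scheme(t, min_count=5)
        assert Setting.CLIMATE_CHAMBER not in scheme.settings_covered
        assert any("climate_chamber" in w for w in warnings)

    def test_fewer_than_two_coverable_settings_is_an_error(self, rng):
        t = _table(
            ["field"] * 20 + ["greenhouse"] * 3,
            rng.uniform(0, 30, 23),
            rng.uniform(0, 1, 23),
        )
        with pytest.raises(InfeasibleBinningError):
            build_bin_scheme(t, min_count=5)

    def test_single_axis_value_degenerate_scheme(self):
        t = _table(
            ["field"] * 5 + ["greenhouse"] * 5, [8.0] * 10, [1.0] * 10
        )
        scheme, _ = build_bin_scheme(t, min_count=5)
        assert scheme.edges == (8.0, 8.0)
        groups, unassigned = assign_bins(t, scheme)
        assert sum(g.n for g in groups) == 10 and len(unassigned) == 0

    def test_search_is_deterministic(self, rng):
        settings_ = ["field", "greenhouse"] * 40
        t = _table(settings_, rng.uniform(0, 30, 80), rng.uniform(0, 1, 80))
        s1, _ = build_bin_scheme(t)
        s2, _ = build_bin_scheme(t.sample(frac=1.0, random_state=0))
        assert s1.edges == s2.edges

    def test_monotone_truth_gives_monotone_bin_means(self, rng):
        # strictly decreasing mean response => post-filter bin means
        # non-increasing across consecutive bins (large n, small noise)
        n = 600
        axis = rng.uniform(0, 30, n)
        resp = 1.0 / (1.0 + (axis / 15.0) ** 2) * np.exp(
            rng.normal(0, 0.05, n)
        )
        t = _table(
            rng.choice(["field", "greenhouse"], n), axis, resp
        )
        scheme, _ = build_bin_scheme(t)
        groups = apply_hampel(assign_bins(t, scheme)[0])
        for s in scheme.settings_covered:
            means = [
                g.mean_response
                for g in sorted(
                    (g for g in groups if g.setting is s),
                    key=lambda g: g.bin_index,
                )
            ]
            assert all(b <= a + 0.05 for a, b in zip(means, means[1:]))


def test_apply_hampel_records_exclusions(rng):
    t = _table(
        ["field"] * 10 + ["greenhouse"] * 10,
        list(rng.uniform(0, 9.9, 20)),
        list(rng.uniform(0.4, 0.6, 19)) + [50.0],
    )
    scheme = BinScheme(
        "grain_yield",
        StressAxis.RELATIVE_EC,
        (0.0, 10.0),
        frozenset({Setting.FIELD, Setting.GREENHOUSE}),
    )
    groups = apply_hampel(assign_bins(t, scheme)[0])
    excluded = [v for g in groups for v, _ in g.excluded]
    assert excluded == [50.0]
    assert count_table(groups).to_numpy().sum() == 19
    summary = bin_summary(groups)
    assert set(summary["setting"]) == {"field", "greenhouse"}


def test_scheme_yaml_round_trip(tmp_path):
    scheme = BinScheme(
        "shoot_dw:vegetative",
        StressAxis.STRESS_INTEGRAL,
        (0.0, 150.0, 400.0),
        frozenset({Setting.GREENHOUSE, Setting.CLIMATE_CHAMBER}),
        min_count=5,
    )
    p = tmp_path / "scheme.yaml"
    scheme_to_yaml(scheme, p)
    assert scheme_from_yaml(p) == scheme
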