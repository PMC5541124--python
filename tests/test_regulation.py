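"""The regulation statistic and contrast classification: closed-form fits,
boundary rules, case-analysis of the group logic, and fixture replay."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoreg import (
    FixtureIntegrityError, RegulationError, TagDistribution, call_regulation,
    classify_contrasts, classify_pair, fit_tag_distribution, load_fixture,
    reproduce_paper_groups,
)

STATUSES = ("up", "down", "unchanged")


def _frame(values, channel=115):
    return pd.DataFrame({
        "accession": [f"A{i}" for i in range(len(values))],
        "channel": channel,
        "log2_ratio": values,
    })


def _calls(pairs, channel=115):
    return pd.DataFrame({
        "accession": [a for a, _ in pairs],
        "channel": channel,
        "log2_ratio": 0.0,
        "deviation": 0.0,
        "status": [s for _, s in pairs],
    })


class TestFitTagDistribution:
    def test_closed_form(self):
        dist = fit_tag_distribution(_frame([-1.0, 0.0, 1.0]), 115)
        assert dist.median == 0.0
        assert dist.sd == pytest.approx(1.0)
        assert dist.n == 3

    def test_against_direct_recomputation(self):
        values = [0.1, -0.1, 0.0, 0.2, -0.2, 3.0]
        dist = fit_tag_distribution(_frame(values), 115)
        assert dist.median == pytest.approx(np.median(values))
        assert dist.sd == pytest.approx(np.std(values, ddof=1))
        calls = call_regulation(_frame(values), dist)
        assert calls.set_index("accession")["status"]["A5"] == "up"

    def test_robust_spread_is_mad_scaled(self):
        values = [0.0, 0.1, -0.1, 0.2, -0.2, 50.0]
        dist = fit_tag_distribution(_frame(values), 115, robust=True)
        med = np.median(values)
        assert dist.sd == pytest.approx(1.4826 * np.median(np.abs(np.array(values) - med)))

    def test_too_few_proteins(self):
        with pytest.raises(RegulationError, match=">= 3"):
            fit_tag_distribution(_frame([0.0, 1.0]), 115)

    def test_degenerate_constant_channel(self):
        with pytest.raises(RegulationError, match="zero"):
            fit_tag_distribution(_frame([0.5, 0.5, 0.5, 0.5]), 115)


class TestCallRegulation:
    def test_boundary_deviation_is_unchanged(self):
        dist = TagDistribution(channel=115, median=0.0, sd=1.0, n=10)
        calls = call_regulation(_frame([2.0, 2.0000001, -2.0, -2.0000001, 0.0]), dist)
        assert calls["status"].tolist() == ["unchanged", "up", "unchanged", "down", "unchanged"]
        assert calls["deviation"].tolist() == pytest.approx([2.0, 2.0000001, -2.0, -2.0000001, 0.0])

    def test_absent_protein_yields_no_call(self):
        dist = TagDistribution(channel=114, median=0.0, sd=1.0, n=10)
        calls = call_regulation(_frame([1.0, 2.0], channel=115), dist)
        assert calls.empty

    def test_affine_rescaling_leaves_statuses_unchanged(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0.3, 0.8, 200)
        base = call_regulation(_frame(values), fit_tag_distribution(_frame(values), 115))
        scaled_values = 3.5 * values + 1.2
        scaled_frame = _frame(scaled_values)
        scaled = call_regulation(scaled_frame, fit_tag_distribution(scaled_frame, 115))
        assert scaled["status"].tolist() == base["status"].tolist()

    def test_null_flag_rate_near_two_sided_normal_tail(self):
        rng = np.random.default_rng(77)
        n = 20_000
        frame = _frame(rng.normal(0, 1, n))
        calls = call_regulation(frame, fit_tag_distribution(frame, 115))
        flagged = (calls["status"] != "unchanged").mean()
        p = 0.0455
        assert abs(flagged - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestClassifyPair:
    @pytest.mark.parametrize("vehicle, u0126, expected", [
        ("up", "unchanged", "group1"),     # e.g. hnRNP D0, log2 3.84
        ("up", "down", "group1"),
        ("down", "unchanged", "group2"),   # e.g. Histone H2B type 1-H, log2 -4.82
        ("down", "up", "group2"),
        ("up", "up", "persistent_up"),     # e.g. S100-A9: top-upregulated, not group 1
        ("down", "down", "persistent_down"),
        ("unchanged", "unchanged", "none"),
        ("unchanged", "up", "none"),
        ("unchanged", "down", "none"),
    ])
    def test_full_case_table(self, vehicle, u0126, expected):
        assert classify_pair(vehicle, u0126) == expected

    def test_unknown_status_is_an_error(self):
        with pytest.raises(RegulationError, match="vehicle"):
            classify_pair("sideways", "up")

    @given(st.sampled_from(STATUSES), st.sampled_from(STATUSES))
    @settings(max_examples=50, deadline=None)
    def test_groups_are_mutually_exclusive(self, vehicle, u0126):
        group = classify_pair(vehicle, u0126)
        assert not (group == "group1" and classify_pair(vehicle, u0126) == "group2")
        assert (group == "group1") <= (vehicle == "up")
        assert (group == "group2") <= (vehicle == "down")


class TestClassifyContrasts:
    def test_vehicle_only_proteins_are_excluded_not_assumed(self):
        vehicle = _calls([("A", "up"), ("B", "down"), ("C", "up")])
        u0126 = _calls([("A", "unchanged"), ("B", "up")], channel=114)
        assignments, vehicle_only = classify_contrasts(vehicle, u0126)
        assert assignments.set_index("accession")["group"].to_dict() == {
            "A": "group1", "B": "group2"}
        assert vehicle_only["accession"].tolist() == ["C"]

    def test_duplicate_accession_is_an_error(self):
        vehicle = _calls([("A", "up"), ("A", "up")])
        with pytest.raises(RegulationError, match="duplicate"):
            classify_contrasts(vehicle, _calls([("A", "up")], channel=114))

    @given(st.lists(st.tuples(st.sampled_from(STATUSES), st.sampled_from(STATUSES)),
                    min_size=1, max_size=25))
    @settings(max_examples=100, deadline=None)
    def test_group_sets_are_disjoint_on_random_call_pairs(self, pairs):
        vehicle = _calls([(f"P{i}", v) for i, (v, _) in enumerate(pairs)])
        u0126 = _calls([(f"P{i}", u) for i, (_, u) in enumerate(pairs)], channel=114)
        assignments, _ = classify_contrasts(vehicle, u0126)
        g1 = set(assignments.loc[assignments["group"] == "group1", "accession"])
        g2 = set(assignments.loc[assignments["group"] == "group2", "accession"])
        assert g1 & g2 == set()


class TestPaperGroupReplay:
    def test_summary_counts_are_deterministic(self):
        a = reproduce_paper_groups(strict=False)
        b = reproduce_paper_groups(strict=False)
        assert a == b
        assert (a.rows_group1, a.rows_group2) == (139, 50)
        assert (a.proteins_group1, a.proteins_group2) == (135, 50)
        assert (a.published_group1, a.published_group2, a.published_total) == (133, 51, 184)

    def test_strict_mode_fails_loudly_on_the_known_mismatch(self):
        """The transcribed source text does not match the published group
        sizes (139/50 rows vs 133/51 stated); strict replay must say so."""
        with pytest.raises(FixtureIntegrityError, match="139/50"):
            reproduce_paper_groups(strict=True)

    def test_group_table_extremes(self):
        t2 = [r.log2_ratio for r in load_fixture("T2")]
        t3 = [r.log2_ratio for r in load_fixture("T3")]
        assert max(t2) == 3.84
        assert min(t3) == -4.82
        assert all(v > 0 for v in t2)   # group 1: SAH-induced upregulation
        assert all(v < 0 for v in t3)   # group 2: SAH-induced downregulation
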