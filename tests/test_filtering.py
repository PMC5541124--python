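"""Target-decoy q-values against an exhaustive-threshold oracle, filter rules,
and monotonicity properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoreg import FilterConfig, FilterError, PSMRecord, apply_filter, estimate_qvalues


def _psm(score, decoy=False, experiment_id="exp1", q=None, psm_id=None):
    return PSMRecord(psm_id=psm_id or f"s{score}", experiment_id=experiment_id, peptide="PEPTIDEK",
                     accession="DECOY_X" if decoy else "ACC", score=float(score),
                     is_decoy=decoy, intensities={114: 1.0, 115: 1.0, 116: 1.0}, q_value=q)


def oracle_qvalues(scores, decoys):
    """Brute-force q-values: enumerate every distinct score as a threshold.

    FDR(t) = #decoys>=t / max(1, #targets>=t); q(s) = min over t <= s.
    Independent of the implementation's vectorized path.
    """
    scores = np.asarray(scores, dtype=float)
    decoys = np.asarray(decoys, dtype=bool)
    thresholds = sorted(set(scores))
    fdr = {}
    for t in thresholds:
        n_decoy = int(np.sum(decoys & (scores >= t)))
        n_target = int(np.sum(~decoys & (scores >= t)))
        fdr[t] = n_decoy / max(1, n_target)
    return [min(fdr[t] for t in thresholds if t <= s) for s in scores]


def test_no_decoys_means_zero_q():
    psms = [_psm(10), _psm(9), _psm(8)]
    assert [p.q_value for p in estimate_qvalues(psms)] == [0.0, 0.0, 0.0]


def test_qvalues_match_hand_computed_example():
    """targets [10, 8, 6, 4], decoys [7, 3]: FDR at thresholds 10/8 is 0,
    at 7 it is 1/2, at 6 it is 1/3, at 4 it is 1/4 (decoy 3 drops out), at 3
    it is 2/4; taking running minima gives q = 0, 0, 1/4, 1/4 for the targets
    and 1/4, 1/2 for the decoys. Frozen from the exhaustive-threshold oracle."""
    psms = [_psm(10), _psm(8), _psm(6), _psm(4), _psm(7, decoy=True), _psm(3, decoy=True)]
    qs = [p.q_value for p in estimate_qvalues(psms)]
    expected = [0.0, 0.0, 0.25, 0.25, 0.25, 0.5]
    assert qs == pytest.approx(expected)
    assert qs == pytest.approx(oracle_qvalues([10, 8, 6, 4, 7, 3],
                                              [0, 0, 0, 0, 1, 1]))


def test_estimation_is_pure():
    psms = [_psm(10), _psm(7, decoy=True), _psm(5)]
    first = [p.q_value for p in estimate_qvalues(psms)]
    second = [p.q_value for p in estimate_qvalues(psms)]
    assert first == second
    assert all(p.q_value is None for p in psms)  # inputs untouched


@given(st.lists(st.tuples(st.integers(0, 50), st.booleans()), min_size=1, max_size=8))
@settings(max_examples=300, deadline=None)
def test_qvalues_match_oracle_on_small_inputs(items):
    """Property: implementation equals exhaustive enumeration on <=8 PSMs."""
    if not any(not d for _, d in items):
        items.append((25, False))
    psms = [_psm(s, decoy=d) for s, d in items]
    got = [p.q_value for p in estimate_qvalues(psms, pool=True)]
    expected = oracle_qvalues([s for s, _ in items], [d for _, d in items])
    assert got == pytest.approx(expected)


@given(st.lists(st.tuples(st.floats(0, 60, allow_nan=False), st.booleans()),
                min_size=2, max_size=30))
@settings(max_examples=200, deadline=None)
def test_qvalues_monotone_nonincreasing_in_score(items):
    if not any(not d for _, d in items):
        items.append((25.0, False))
    psms = [_psm(s, decoy=d) for s, d in items]
    annotated = estimate_qvalues(psms, pool=True)
    ordered = sorted(annotated, key=lambda p: p.score)
    for lo, hi in zip(ordered, ordered[1:]):
        assert hi.q_value <= lo.q_value + 1e-12


def test_per_experiment_grouping_is_the_default():
    # exp2 has decoys above every target; pooling would contaminate exp1
    psms = [_psm(30), _psm(20), _psm(40, decoy=True, experiment_id="exp2"),
            _psm(10, experiment_id="exp2")]
    qs = {p.psm_id: p.q_value for p in estimate_qvalues(psms)}
    assert qs["s30"] == 0.0 and qs["s20"] == 0.0
    assert qs["s10"] == 1.0
    pooled = {p.psm_id: p.q_value for p in estimate_qvalues(psms, pool=True)}
    assert pooled["s30"] > 0.0


def test_empty_and_all_decoy_inputs_are_errors():
    with pytest.raises(FilterError, match="empty"):
        estimate_qvalues([])
    with pytest.raises(FilterError, match="no target"):
        estimate_qvalues([_psm(10, decoy=True)])


class TestApplyFilter:
    def test_score_floor_removes_high_confidence_low_score(self):
        psms = [_psm(17.9, q=0.0), _psm(18.0, q=0.0), _psm(50, q=0.02)]
        kept = apply_filter(psms, FilterConfig(fdr_threshold=0.01, score_floor=18.0))
        assert [p.score for p in kept] == [18.0]

    def test_decoys_never_pass(self):
        psms = [_psm(50, decoy=True, q=0.0), _psm(40, q=0.0)]
        assert [p.is_decoy for p in apply_filter(psms)] == [False]

    def test_requires_qvalues(self):
        with pytest.raises(FilterError, match="q-value"):
            apply_filter([_psm(30)])

    def test_order_preserved_and_monotone_in_config(self):
        rng = np.random.default_rng(4)
        psms = [_psm(s, decoy=bool(d)) for s, d in
                zip(rng.normal(30, 10, 200), rng.random(200) < 0.3)]
        annotated = estimate_qvalues(psms, pool=True)
        tight = apply_filter(annotated, FilterConfig(0.01, 25.0))
        loose = apply_filter(annotated, FilterConfig(0.05, 20.0))
        assert set(p.psm_id for p in tight) <= set(p.psm_id for p in loose)
        ids = [p.psm_id for p in annotated if not p.is_decoy]
        assert [p.psm_id for p in loose] == [i for i in ids
                                             if i in {p.psm_id for p in loose}]


def test_qvalues_agree_with_pyteomics():
    """Independent cross-check against pyteomics' target-decoy q-values.

    Conventions diverge only above q = 1 (neither library clips, and the
    denominators differ once decoys outnumber targets); clipped at 1 the two
    must agree exactly — any PSM that matters for filtering has q << 1.
    """
    aux = pytest.importorskip("pyteomics.auxiliary")
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = int(rng.integers(2, 40))
        scores = rng.integers(0, 30, n).astype(float)
        decoys = rng.random(n) < 0.4
        if decoys.all():
            decoys[0] = False
        psms = [_psm(s, decoy=bool(d), psm_id=str(i))
                for i, (s, d) in enumerate(zip(scores, decoys))]
        ours = {p.psm_id: min(p.q_value, 1.0) for p in estimate_qvalues(psms, pool=True)}
        theirs = aux.qvalues(psms, key=lambda p: p.score, is_decoy=lambda p: p.is_decoy,
                             reverse=True, remove_decoy=False, formula=1, full_output=True)
        for row in theirs:
            assert ours[row["psm"].psm_id] == pytest.approx(min(float(row["q"]), 1.0))


def test_realized_fdr_bounded_on_separated_scores():
    """With target ~N(40,5) and decoy ~N(10,5), the decoy-estimated FDR among
    retained PSMs stays within 2x nominal at 10,000 PSMs (seed-pinned)."""
    rng = np.random.default_rng(123)
    n = 10_000
    is_decoy = rng.random(n) < 0.5
    scores = np.where(is_decoy, rng.normal(10, 5, n), rng.normal(40, 5, n))
    psms = [_psm(s, decoy=bool(d)) for s, d in zip(scores, is_decoy)]
    kept = apply_filter(estimate_qvalues(psms, pool=True), FilterConfig(0.01, 18.0))
    assert kept, "filter should retain the bulk of targets"
    threshold = min(p.score for p in kept)
    n_decoy_above = int(np.sum(is_decoy & (scores >= threshold)))
    realized = n_decoy_above / len(kept)
    assert realized <= 2 * 0.01
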