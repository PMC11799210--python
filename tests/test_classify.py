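"""Two-/three-timer occupancy classification and assemblage summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thermobias import (
    RESPONSE_LEVELS,
    TimeBinSequence,
    classify_responses,
    classify_three_timer,
    classify_two_timer,
    jaccard_turnover,
    summarize_assemblage,
)
from thermobias.classify import attach_bias, pool_levels, summarize_assemblages
from thermobias.occurrences import RangeTable
from conftest import make_occurrence_frame


def presence_dict(im1=False, i=False, i1=False, i2=False, boundary=2):
    return {boundary - 1: im1, boundary: i, boundary + 1: i1, boundary + 2: i2}


# ---------------------------------------------------------------------------
# two-timer rule examples (interior boundary, away from edges)
# ---------------------------------------------------------------------------

def test_two_timer_immigrating():
    p = presence_dict(i1=True, i2=True)
    assert classify_two_timer(p, 2, fad=0, lad=5) == RESPONSE_LEVELS["immigrating"]


def test_two_timer_originating_requires_fad_at_arrival():
    p = presence_dict(i1=True, i2=True)
    assert classify_two_timer(p, 2, fad=3, lad=5) == RESPONSE_LEVELS["originating"]


def test_two_timer_extinct_requires_lad_at_i():
    p = presence_dict(im1=True, i=True)
    assert classify_two_timer(p, 2, fad=0, lad=2) == RESPONSE_LEVELS["extinct"]
    assert classify_two_timer(p, 2, fad=0, lad=4) == RESPONSE_LEVELS["extirpated"]


def test_two_timer_persisting_ignores_outer_bins():
    for im1 in (False, True):
        for i2 in (False, True):
            p = presence_dict(im1=im1, i=True, i1=True, i2=i2)
            assert classify_two_timer(p, 2, fad=0, lad=5) == RESPONSE_LEVELS["persisting"]


def test_two_timer_unclassifiable_singleton():
    p = presence_dict(i=True)  # present only at i, no i-1 record
    assert classify_two_timer(p, 2, fad=2, lad=2) is None


def test_two_timer_missing_range_assigns_nonextreme():
    p = presence_dict(i1=True, i2=True)
    with pytest.warns(UserWarning):
        assert classify_two_timer(p, 2, fad=None, lad=None) == RESPONSE_LEVELS["immigrating"]


# Frozen expectation table over all 16 presence patterns (interior boundary,
# FAD/LAD away from the focal boundary). Hand-derived from the rules.
TWO_TIMER_TABLE = {
    # (i-1, i, i+1, i+2): level or None
    (0, 0, 0, 0): None,
    (0, 0, 0, 1): None,
    (0, 0, 1, 0): None,          # upper two-timer incomplete
    (0, 0, 1, 1): 2,             # immigrating
    (0, 1, 0, 0): None,          # lower two-timer incomplete
    (0, 1, 0, 1): None,
    (0, 1, 1, 0): 3,
    (0, 1, 1, 1): 3,
    (1, 0, 0, 0): None,
    (1, 0, 0, 1): None,
    (1, 0, 1, 0): None,
    (1, 0, 1, 1): 2,
    (1, 1, 0, 0): 4,             # extirpated
    (1, 1, 0, 1): 4,
    (1, 1, 1, 0): 3,
    (1, 1, 1, 1): 3,
}


def test_two_timer_full_truth_table():
    for pattern, expected in TWO_TIMER_TABLE.items():
        p = presence_dict(*map(bool, pattern))
        got = classify_two_timer(p, 2, fad=0, lad=5)
        assert got == expected, f"pattern {pattern}: got {got}, expected {expected}"


THREE_TIMER_TABLE = {
    (0, 0, 0): None,
    (0, 0, 1): None,
    (0, 1, 0): None,
    (0, 1, 1): 2,                # immigrating (absent i-1, present i and i+1)
    (1, 0, 0): None,
    (1, 0, 1): None,
    (1, 1, 0): 4,                # extirpated
    (1, 1, 1): 3,                # persisting needs all three bins
}


def test_three_timer_truth_table_and_examples():
    for (im1, i, i1), expected in THREE_TIMER_TABLE.items():
        p = {1: bool(im1), 2: bool(i), 3: bool(i1)}
        got = classify_three_timer(p, 2, fad=0, lad=5)
        assert got == expected, f"pattern {(im1, i, i1)}"
    # originating: FAD at i
    assert classify_three_timer({1: False, 2: True, 3: True}, 2, fad=2, lad=5) == 1
    assert classify_three_timer({1: True, 2: True, 3: False}, 2, fad=0, lad=2) == 5


# ---------------------------------------------------------------------------
# edge relaxation
# ---------------------------------------------------------------------------

def test_edge_relaxation_first_boundary():
    # Extirpated at the first boundary: the i-1 record may come from anywhere
    # in the dataset in the flanking bin.
    p = {-1: False, 0: True, 1: False}
    assert classify_two_timer(p, 0, fad=-1, lad=3, global_flank_before=True) == 4
    assert classify_two_timer(p, 0, fad=-1, lad=3, global_flank_before=False) is None


def test_edge_relaxation_last_boundary():
    n = 6
    p = {4: False, 5: True, 6: False}
    got = classify_two_timer(p, 4, n_bins=n, fad=0, lad=6, global_flank_after=True)
    assert got == RESPONSE_LEVELS["immigrating"]
    assert classify_two_timer(p, 4, n_bins=n, fad=0, lad=6, global_flank_after=False) is None


def test_edge_relaxation_still_needs_regional_occurrence():
    # Flank presence alone, with no regional record at i or i+1, classifies nothing.
    p = {-1: False, 0: False, 1: False}
    assert classify_two_timer(p, 0, fad=-1, lad=3, global_flank_before=True) is None


# ---------------------------------------------------------------------------
# structural invariants
# ---------------------------------------------------------------------------

def test_extreme_levels_are_subsets_of_their_patterns():
    """originating matches the immigrating pattern; extinct the extirpated one."""
    rng = np.random.default_rng(0)
    for _ in range(300):
        pattern = {k: bool(rng.integers(2)) for k in range(-1, 7)}
        fad = int(rng.integers(-1, 7))
        lad = int(rng.integers(fad, 7))
        i = int(rng.integers(0, 5))
        with_range = classify_two_timer(pattern, i, fad=fad, lad=lad)
        away = classify_two_timer(pattern, i, fad=-1, lad=6)
        if with_range == 1:
            assert away in (1, 2)
        if with_range == 5:
            assert away in (4, 5)


def test_classification_is_single_valued(small_world, seq):
    occ = small_world.occurrences.rename(columns={"true_region": "region_id"})
    records, report = classify_responses(occ, small_world.range_table, bin_sequence=seq)
    assert not records.duplicated(["species", "region_id", "boundary", "scheme"]).any()
    assert report.n_classified == len(records)
    assert report.n_classified + report.n_unclassifiable == report.n_candidates


# ---------------------------------------------------------------------------
# bias attachment and pooling
# ---------------------------------------------------------------------------

def _mini_records(seq):
    occ = make_occurrence_frame(
        [
            # species a persists over Spinatum-Tenuicostatum in region 0
            ("a", 0, "Spinatum", 22.0),
            ("a", 0, "Tenuicostatum", 24.0),
            # species b immigrates at Tenuicostatum (present Tenui + Exaratum)
            ("b", 0, "Exaratum", 28.0),
            ("b", 0, "Tenuicostatum", 24.0),
            ("b", 1, "Margaritatus", 25.0),
            # ambient anchors for region 0
            ("c", 0, "Spinatum", 22.0),
            ("c", 0, "Tenuicostatum", 24.0),
        ]
    )
    rt = compute = None
    from thermobias import compute_range_table

    rt = compute_range_table(occ, seq)
    records, _ = classify_responses(occ, rt, bin_sequence=seq)
    return occ, records


def test_attach_bias_contexts(seq):
    from thermobias.metrics import regional_climate, sti_table

    occ, records = _mini_records(seq)
    sti = sti_table(occ, bin_sequence=seq)
    clim = regional_climate(occ, bin_sequence=seq)
    out, dropped = attach_bias(records, sti, clim)
    out = out.set_index(["species", "boundary"])
    # persisting species a at Spinatum-Tenuicostatum: context is time i
    row = out.loc[("a", "Spinatum-Tenuicostatum")]
    assert row["ambient_T"] == 22.0
    assert row["thermal_bias"] == pytest.approx(row["sti"] - 22.0)
    # immigrating species b at the same boundary: context is time i+1
    row_b = out.loc[("b", "Spinatum-Tenuicostatum")]
    assert row_b["ambient_T"] == 24.0


def test_pooling_rules():
    rec = pd.DataFrame({"response": [1, 2, 3, 4, 5]})
    assert sorted(pool_levels(rec, "merged")["response"]) == [2, 2, 3, 4, 4]
    assert sorted(pool_levels(rec, "five_level")["response"]) == [1, 2, 3, 4, 5]
    assert sorted(pool_levels(rec, "three_level")["response"]) == [2, 3, 4]
    with pytest.raises(ValueError):
        pool_levels(rec, "bogus")


# ---------------------------------------------------------------------------
# Jaccard turnover and assemblage summaries
# ---------------------------------------------------------------------------

def test_jaccard_examples():
    assert jaccard_turnover({"a", "b", "c"}, {"a", "b", "c"}) == 0.0
    assert jaccard_turnover({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(0.5)
    assert jaccard_turnover({"a"}, {"b"}) == 1.0
    assert jaccard_turnover(set(), set()) == 0.0


@settings(max_examples=100, deadline=None)
@given(
    a=st.sets(st.integers(0, 12), max_size=10),
    b=st.sets(st.integers(0, 12), max_size=10),
)
def test_jaccard_is_a_metric_on_sets(a, b):
    d = jaccard_turnover(a, b)
    assert 0 <= d <= 1
    assert d == jaccard_turnover(b, a)
    assert (d == 0) == (a == b)


def test_summarize_assemblage_fixture():
    records = pd.DataFrame(
        {"response": [3, 3, 2], "species": ["b", "c", "d"]}
    )
    out = summarize_assemblage(records, {"a", "b", "c"}, {"b", "c", "d"})
    assert out["jaccard_turnover"] == pytest.approx(0.5)
    assert out["pct_immigrating"] == pytest.approx(100 / 3)
    assert out["pct_persisting"] == 100.0


def test_summary_percentages_close(tracking_run, seq):
    summaries = tracking_run.summaries
    cur = summaries[summaries["n_current_classified"] > 0]
    total = cur["pct_persisting"] + cur["pct_extirpated"] + cur["pct_extinct"]
    np.testing.assert_allclose(total, 100.0)
    for col in ("pct_immigrating", "pct_originating"):
        vals = summaries[col].dropna()
        assert ((vals >= 0) & (vals <= 100)).all()
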