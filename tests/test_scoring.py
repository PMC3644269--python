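"""Cell-level scoring: cluster capping, ratio, classification, reflex."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import her2fish as hf
from conftest import make_cells


# ---------------------------------------------------------------------------
# effective HER2 count (cluster capping)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "her2,cluster,expected",
    [
        (30, True, 16),   # flagged cluster counts as exactly 16 signals
        (4, False, 4),    # below the cap: identity
        (16, False, 16),  # at the cap: unchanged
        (3, True, 16),    # the flag wins even for a low raw count
    ],
)
def test_effective_her2(her2, cluster, expected, thresholds):
    assert hf.effective_her2(hf.CellObservation(her2, 2, cluster), thresholds) == expected


def test_implicit_cluster_capped_with_warning(thresholds):
    """A count >16 without the flag meets the cluster definition: capped, warned."""
    with pytest.warns(UserWarning, match="cluster"):
        assert hf.effective_her2(hf.CellObservation(20, 2), thresholds) == 16


def test_negative_counts_rejected():
    with pytest.raises(hf.InputError):
        hf.CellObservation(-1, 2)
    with pytest.raises(hf.InputError):
        hf.CellObservation(2, -3)


# ---------------------------------------------------------------------------
# tumour-level scoring
# ---------------------------------------------------------------------------

def test_score_cells_homogeneous(thresholds):
    score = hf.score_cells(make_cells([(60, 4, 2)]), thresholds)
    assert score.mean_her2 == 4.0
    assert score.mean_cep17 == 2.0
    assert score.ratio == 2.0
    assert score.frac_cells_ratio_gt_high == 0.0
    assert score.asco_call is hf.AmplificationCall.EQUIVOCAL


def test_score_cells_mixture(thresholds):
    """30 cells at 10/2 and 30 at 2/2: ratio 3.0, half the cells above 2.2."""
    score = hf.score_cells(make_cells([(30, 10, 2), (30, 2, 2)]), thresholds)
    assert score.ratio == pytest.approx(3.0, abs=1e-12)
    assert score.frac_cells_ratio_gt_high == pytest.approx(0.5, abs=1e-12)
    assert score.heterogeneity is False  # 50% is not < 50%


def test_score_cells_caps_before_averaging(thresholds):
    with pytest.warns(UserWarning, match="cluster"):
        score = hf.score_cells(make_cells([(60, 18, 2)]), thresholds)
    assert score.mean_her2 == 16.0
    assert score.ratio == 8.0


def test_score_cells_errors(thresholds):
    with pytest.raises(hf.InputError):
        hf.score_cells([], thresholds)
    with pytest.raises(hf.UndefinedRatioError):
        hf.score_cells(make_cells([(10, 4, 0)]), thresholds)


def test_cep17_zero_cells_kept_in_means_excluded_from_tally(thresholds):
    """CEP17=0 cells contribute to the means but have no per-cell ratio."""
    cells = make_cells([(9, 10, 2), (1, 10, 0)])
    with pytest.warns(UserWarning, match="CEP17=0"):
        score = hf.score_cells(cells, thresholds)
    assert score.mean_cep17 == pytest.approx(1.8)
    assert score.mean_her2 == 10.0
    assert score.frac_cells_ratio_gt_high == 1.0  # 9 evaluable cells, all >2.2


# ---------------------------------------------------------------------------
# classification rules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ratio,expected",
    [
        (1.79, "non_amplified"),
        (1.80, "equivocal"),   # lower boundary is inside the equivocal band
        (2.00, "equivocal"),
        (2.20, "equivocal"),   # upper boundary is inside the band
        (2.21, "amplified"),
        (2.62, "amplified"),
        (1.49, "non_amplified"),
        (2.05, "equivocal"),
    ],
)
def test_asco_boundaries(ratio, expected, thresholds):
    assert hf.classify_asco(ratio, thresholds).value == expected


@pytest.mark.parametrize(
    "ratio,expected",
    [(2.0, "amplified"), (1.99, "non_amplified"), (3.14, "amplified")],
)
def test_alt_ratio_cutoff_is_inclusive(ratio, expected, thresholds):
    assert hf.classify_alt_ratio(ratio, thresholds).value == expected


@pytest.mark.parametrize(
    "mean,expected",
    [(6.41, "amplified"), (6.0, "non_amplified"), (0.0, "non_amplified")],
)
def test_mean_copies_cutoff_is_strict(mean, expected, thresholds):
    assert hf.classify_mean_copies(mean, thresholds).value == expected


def test_nonfinite_ratio_rejected(thresholds):
    for bad in (math.nan, math.inf):
        with pytest.raises(hf.InputError):
            hf.classify_asco(bad, thresholds)


@pytest.mark.parametrize("value,expected", [(3.01, True), (3.00, False), (2.24, False)])
def test_polysomy_strictly_above_3(value, expected, thresholds):
    assert hf.assess_polysomy(value, thresholds) is expected


def test_heterogeneity_bounds_are_strict(thresholds):
    def cohort(n_high, n_total):
        return make_cells([(n_high, 10, 2), (n_total - n_high, 2, 2)])

    assert hf.assess_heterogeneity(cohort(6, 60), thresholds) is True    # 10%
    assert hf.assess_heterogeneity(cohort(3, 60), thresholds) is False   # exactly 5%
    assert hf.assess_heterogeneity(cohort(30, 60), thresholds) is False  # exactly 50%
    assert hf.assess_heterogeneity(cohort(4, 60), thresholds) is True    # 6.7%


def test_cluster_positivity_at_one_percent(thresholds):
    base = [(99, 4, 2)]
    assert hf.assess_cluster_positive(make_cells(base + [(1, 30, 2, True)]), thresholds)
    assert not hf.assess_cluster_positive(make_cells([(60, 4, 2)]), thresholds)
    # 1/60 = 1.67% >= 1%
    assert hf.assess_cluster_positive(make_cells([(59, 4, 2), (1, 20, 2, True)]), thresholds)


# ---------------------------------------------------------------------------
# equivocal reflex
# ---------------------------------------------------------------------------

def test_reflex_not_triggered_outside_band(thresholds):
    initial = make_cells([(60, 6, 2)])  # ratio 3.0
    score = hf.score_with_reflex(initial, (), thresholds)
    assert score.n_cells == 60
    assert score.reflex_performed is False
    # bit-identical to plain scoring of the same 60 cells
    assert score == hf.score_cells(initial, thresholds)

    below = make_cells([(60, 3, 2)])  # ratio 1.5 < 1.8
    assert hf.score_with_reflex(below, (), thresholds).reflex_performed is False


def test_reflex_pools_100_cells(thresholds):
    initial = make_cells([(60, 4, 2)])  # ratio 2.0: equivocal
    extra = make_cells([(40, 6, 2)])
    score = hf.score_with_reflex(initial, extra, thresholds)
    assert score.reflex_performed is True
    assert score.n_cells == thresholds.n_reflex_total
    # pooled ratio recomputed over all 100 cells
    assert score.ratio == pytest.approx((60 * 4 + 40 * 6) / (100 * 2), abs=1e-12)


def test_reflex_required_error(thresholds):
    with pytest.raises(hf.ReflexRequiredError):
        hf.score_with_reflex(make_cells([(60, 4, 2)]), (), thresholds)


def test_reflex_cell_count_contract(thresholds):
    with pytest.raises(hf.InputError):
        hf.score_with_reflex(make_cells([(59, 4, 2)]), (), thresholds)
    with pytest.raises(hf.InputError):
        hf.score_with_reflex(make_cells([(60, 6, 2)]), make_cells([(30, 6, 2)]), thresholds)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

cell_strategy = st.tuples(
    st.integers(min_value=0, max_value=25),
    st.integers(min_value=0, max_value=8),
    st.booleans(),
)


def _oracle_score(cells, th):
    """Independent straight-line tally of all scoring quantities."""
    eff = []
    for c in cells:
        e = th.cluster_cap if (c.cluster or c.her2 > th.cluster_cap) else c.her2
        eff.append(e)
    mean_her2 = sum(eff) / len(cells)
    mean_cep17 = sum(c.cep17 for c in cells) / len(cells)
    ratio = mean_her2 / mean_cep17
    evaluable = [(e, c.cep17) for e, c in zip(eff, cells) if c.cep17 > 0]
    frac = sum(1 for e, k in evaluable if e / k > th.ratio_high) / len(evaluable)
    return mean_her2, mean_cep17, ratio, frac


@settings(max_examples=200, derandomize=True)
@given(st.lists(cell_strategy, min_size=1, max_size=20))
def test_score_cells_matches_straight_line_oracle(raw):
    """Vectorised scoring agrees with an independent per-cell tally."""
    th = hf.ScoringThresholds()
    cells = [hf.CellObservation(h, c, f) for h, c, f in raw]
    if all(c.cep17 == 0 for c in cells):
        with pytest.raises(hf.UndefinedRatioError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hf.score_cells(cells, th)
        return
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        score = hf.score_cells(cells, th)
    mean_her2, mean_cep17, ratio, frac = _oracle_score(cells, th)
    assert score.mean_her2 == pytest.approx(mean_her2, abs=1e-12)
    assert score.mean_cep17 == pytest.approx(mean_cep17, abs=1e-12)
    assert score.ratio == pytest.approx(ratio, abs=1e-12)
    assert score.frac_cells_ratio_gt_high == pytest.approx(frac, abs=1e-12)
    assert score.asco_call == hf.classify_asco(ratio, th)
    assert score.mean_copies_call == hf.classify_mean_copies(mean_her2, th)


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(st.integers(min_value=0, max_value=40), min_size=1, max_size=30),
    st.integers(min_value=0, max_value=29),
    st.integers(min_value=1, max_value=40),
)
def test_cluster_cap_monotonic_and_bounded(her2_counts, idx, bump):
    """Raising any HER2 count never lowers the mean, which never exceeds 16."""
    th = hf.ScoringThresholds()

    def mean_eff(counts):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eff = [hf.effective_her2(hf.CellObservation(h, 2), th) for h in counts]
        return sum(eff) / len(eff)

    base = mean_eff(her2_counts)
    assert base <= th.cluster_cap
    idx = idx % len(her2_counts)
    bumped = list(her2_counts)
    bumped[idx] += bump
    assert mean_eff(bumped) >= base - 1e-15


def test_asco_partition_is_exhaustive_and_exclusive(thresholds):
    for ratio in np.linspace(0.01, 10.0, 2001):
        call = hf.classify_asco(float(ratio), thresholds)
        expected = (
            "amplified"
            if ratio > thresholds.ratio_high
            else "equivocal"
            if ratio >= thresholds.ratio_low
            else "non_amplified"
        )
        assert call.value == expected


# ---------------------------------------------------------------------------
# table I/O and per-sample scoring
# ---------------------------------------------------------------------------

def test_score_table_roundtrip(tmp_path, thresholds):
    import pandas as pd

    rows = []
    for cid in range(1, 101):
        rows.append({"sample_id": "S1", "method": "A", "cell_id": cid, "her2": 4, "cep17": 2, "cluster": 0})
    for cid in range(1, 61):
        rows.append({"sample_id": "S2", "method": "A", "cell_id": cid, "her2": 10, "cep17": 2, "cluster": 0})
    df = pd.DataFrame(rows)
    path = tmp_path / "cells.tsv"
    df.to_csv(path, sep="\t", index=False)
    scores = hf.score_table(hf.read_cell_table(path), thresholds)
    scores = scores.set_index("sample_id")
    # S1 is equivocal at 60 cells -> reflex consumed all 100
    assert scores.loc["S1", "reflex_performed"]
    assert scores.loc["S1", "n_cells"] == 100
    # S2 is clearly amplified -> scored on the 60-cell initial read
    assert not scores.loc["S2", "reflex_performed"]
    assert scores.loc["S2", "asco_call"] == "amplified"


def test_read_cell_table_requires_columns(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("sample_id,her2\nS1,4\n")
    with pytest.raises(hf.InputError, match="cep17"):
        hf.read_cell_table(path)


def test_few_areas_warns_not_errors(thresholds):
    cells = [hf.CellObservation(4, 2, area="a1") for _ in range(60)]
    with pytest.warns(UserWarning, match="area"):
        score = hf.score_cells(cells, thresholds)
    assert score.ratio == 2.0
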