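"""Standard and robust per-cell summary statistics."""

import numpy as np
import pytest
from scipy import stats

from rezddm import TrialSet, standard_summaries, robust_summaries, summarize_dataset
from rezddm.summaries import IQR_NORMAL_DIVISOR, cells_to_frame


def _trials(rts, acc=None):
    rts = np.asarray(rts, dtype=float)
    if acc is None:
        acc = np.ones(rts.size, dtype=int)
    return TrialSet(rt=rts, accuracy=np.asarray(acc))


def test_standard_summaries_hand_computed():
    cell = standard_summaries(_trials([1, 2, 3, 4], [1, 1, 0, 1]))
    assert cell.loc == pytest.approx(2.5)
    assert cell.scale == pytest.approx(5 / 3)
    assert cell.n_correct == 3 and cell.n == 4


def test_equal_rts_have_zero_scale():
    for f in (standard_summaries, robust_summaries):
        cell = f(_trials([0.7] * 6))
        assert cell.scale == pytest.approx(0.0, abs=1e-30)
        assert cell.loc == pytest.approx(0.7)


def test_median_ignores_outlier():
    cell = robust_summaries(_trials([1, 2, 3, 4, 100]))
    assert cell.loc == 3.0


def test_minimum_cell_size():
    with pytest.raises(ValueError):
        standard_summaries(_trials([1, 2, 3]))
    with pytest.raises(ValueError):
        robust_summaries(_trials([1, 2, 3]))


def test_normal_consistency_divisor_is_analytic():
    """IQR of N(0,1) = 2 * Phi^-1(0.75) = 1.349 to 3 decimals."""
    assert 2 * stats.norm.ppf(0.75) == pytest.approx(IQR_NORMAL_DIVISOR, abs=5e-4)


def test_iqr_variance_consistent_for_normal(rng):
    """Var_IQR converges to the true variance on large normal samples."""
    x = rng.normal(5.0, 1.0, 100_000)
    cell = robust_summaries(_trials(x))
    std = standard_summaries(_trials(x))
    assert cell.scale == pytest.approx(1.0, rel=0.02)
    assert cell.scale / std.scale == pytest.approx(1.0, rel=0.02)


def test_breakdown_robustness(rng):
    """Median and IQR are untouched when one upper-tail RT explodes."""
    x = np.sort(rng.normal(2.0, 0.3, 101))
    corrupted = x.copy()
    corrupted[-1] = 1e9
    a = robust_summaries(_trials(x))
    b = robust_summaries(_trials(corrupted))
    assert a.loc == b.loc
    assert a.scale == b.scale


def test_clean_sample_matches_forward_moments(rng):
    """Both summary flavours estimate the decision-process moments."""
    from rezddm import DDMParams, forward_moments, sample_trials

    p = DDMParams(1.5, 3.0, 0.3)
    m = forward_moments(p)
    ts = sample_trials(p, 50_000, rng)
    std = standard_summaries(ts)
    rob = robust_summaries(ts)
    assert std.loc == pytest.approx(m.mrt, rel=0.02)
    assert std.scale == pytest.approx(m.vrt, rel=0.05)
    assert std.n_correct == rob.n_correct
    # robust location is the median, not the mean: only roughly comparable
    assert abs(rob.loc - std.loc) < 0.2


class TestSummarizeDataset:
    def test_cell_count_and_tags(self, small_dataset):
        _, ind, data = small_dataset
        cells = summarize_dataset(data, "standard", rt_scope="all")
        assert len(cells) == ind.n_participants * 2
        assert all(c.method == "standard" for c in cells)
        assert all(c.n == c.n_total == 40 for c in cells)

    def test_rt_scope_changes_n_not_n_correct(self, small_dataset):
        _, _, data = small_dataset
        all_cells = summarize_dataset(data, "standard", rt_scope="all")
        cor_cells = summarize_dataset(data, "standard", rt_scope="correct_only")
        for a, c in zip(all_cells, cor_cells):
            assert c.n == a.n_correct == c.n_correct
            assert c.n_total == a.n_total == 40

    def test_methods_agree_on_location(self, small_dataset):
        _, _, data = small_dataset
        std = summarize_dataset(data, "standard", rt_scope="all")
        rob = summarize_dataset(data, "robust", rt_scope="all")
        locs = np.array([[s.loc, r.loc] for s, r in zip(std, rob)])
        assert np.corrcoef(locs.T)[0, 1] > 0.95
        assert all(s.n_correct == r.n_correct for s, r in zip(std, rob))

    def test_contaminated_cell_shifts_standard_more(self, rng):
        """One delayed trial moves the mean by ~offset/n, the median barely."""
        from rezddm import DDMParams, sample_trials

        ts = sample_trials(DDMParams(1.0, 2.5, 0.3), 80, rng)
        rt2 = ts.rt.copy()
        rt2[0] += 2.5
        dirty = TrialSet(rt=rt2, accuracy=ts.accuracy)
        d_std = standard_summaries(dirty).loc - standard_summaries(ts).loc
        d_rob = robust_summaries(dirty).loc - robust_summaries(ts).loc
        assert d_std == pytest.approx(2.5 / 80, abs=1e-12)
        assert abs(d_rob) < d_std

    def test_empty_cell_error_names_cell(self, small_dataset):
        import pandas as pd
        from rezddm import Dataset

        _, _, data = small_dataset
        df = data.df.copy()
        df.loc[(df["participant"] == 0), "accuracy"] = 0
        with pytest.raises(ValueError, match="participant=0"):
            summarize_dataset(Dataset(df), "standard", rt_scope="correct_only")

    def test_invalid_arguments(self, small_dataset):
        _, _, data = small_dataset
        with pytest.raises(ValueError):
            summarize_dataset(data, "mad")
        with pytest.raises(ValueError):
            summarize_dataset(data, "standard", rt_scope="weird")


def test_cells_to_frame(small_dataset):
    _, ind, data = small_dataset
    frame = cells_to_frame(summarize_dataset(data, "robust", rt_scope="all"))
    assert len(frame) == ind.n_participants * 2
    assert list(frame.columns) == [
        "participant", "condition", "n", "n_correct", "loc", "scale", "method", "n_total",
    ]
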