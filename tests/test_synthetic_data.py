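"""Hierarchical dataset generator and the two-stage contamination procedure."""

import numpy as np
import pandas as pd
import pytest

from rezddm import (
    PRESETS,
    PopulationParams,
    draw_population,
    draw_individuals,
    generate_dataset,
    contaminate,
)
from rezddm.synthetic_data import SIGMA2_NU, SIGMA2_ALPHA, SIGMA2_TAU, TAU_FLOOR


def test_population_draw_respects_preset_ranges(rng):
    for _ in range(200):
        pop = draw_population("main", 0.2, rng)
        assert -3 <= pop.mu_nu <= 3
        assert 2 <= pop.mu_alpha <= 4
        assert 0.2 <= pop.mu_tau <= 0.4
        assert (pop.sigma2_nu, pop.sigma2_alpha, pop.sigma2_tau) == (
            SIGMA2_NU, SIGMA2_ALPHA, SIGMA2_TAU,
        )
    hh = draw_population("high-nu/high-alpha", 0.0, rng)
    assert 2 <= hh.mu_nu <= 3 and 3.5 <= hh.mu_alpha <= 4
    ll = draw_population("low-nu/low-alpha", 0.0, rng)
    assert 0 <= ll.mu_nu <= 1 and 2 <= ll.mu_alpha <= 2.5
    with pytest.raises(ValueError):
        draw_population("nope", 0.0, rng)


def test_population_draw_uniform_symmetry(rng):
    draws = np.array([draw_population("main", 0, rng).mu_nu for _ in range(10_000)])
    se = np.sqrt((6**2 / 12) / draws.size)  # U(-3,3) variance / n
    assert abs(draws.mean()) < 3 * se


@pytest.mark.parametrize("beta", [0.0, 0.4])
def test_individual_drift_effect(rng, beta):
    """Condition-1 drift exceeds condition-0 drift by beta on average."""
    pop = PopulationParams(0.5, beta, SIGMA2_NU, 3.0, SIGMA2_ALPHA, 0.3, SIGMA2_TAU)
    ind = draw_individuals(pop, 10_000, rng)
    diff = ind.nu[:, 1] - ind.nu[:, 0]
    se = diff.std(ddof=1) / np.sqrt(diff.size)
    assert abs(diff.mean() - beta) < 3 * se
    # each column keeps the stated dispersion
    assert ind.nu[:, 0].var(ddof=1) == pytest.approx(SIGMA2_NU, rel=0.05)
    assert ind.nu[:, 1].var(ddof=1) == pytest.approx(SIGMA2_NU, rel=0.05)


def test_individual_positivity_rules(rng):
    pop = PopulationParams(0.0, 0.0, SIGMA2_NU, 0.5, SIGMA2_ALPHA, 0.1, SIGMA2_TAU)
    ind = draw_individuals(pop, 5_000, rng)
    assert np.all(ind.alpha > 0)
    assert np.all(ind.tau >= TAU_FLOOR)


def test_dataset_bookkeeping(small_dataset):
    _, ind, data = small_dataset
    assert len(data) == ind.n_participants * 2 * 40
    assert data.trials_per_cell == 40
    assert (data.df["contaminant"] == "none").all()


def test_generation_deterministic():
    pop = PopulationParams(1.0, 0.2, SIGMA2_NU, 3.0, SIGMA2_ALPHA, 0.3, SIGMA2_TAU)
    frames = []
    for _ in range(2):
        rng = np.random.default_rng(99)
        ind = draw_individuals(pop, 3, rng)
        frames.append(generate_dataset(ind, 10, rng).df)
    pd.testing.assert_frame_equal(frames[0], frames[1])


def test_high_drift_cell_accuracy(rng):
    """nu=3, alpha=3 puts accuracy near 1 (pc = 1/(1+e^-9))."""
    from rezddm import DDMParams, sample_trials

    ts = sample_trials(DDMParams(3.0, 3.0, 0.3), 2_000, rng)
    assert ts.accuracy.mean() > 0.99


@pytest.fixture(scope="module")
def contaminated():
    rng = np.random.default_rng(7)
    pop = PopulationParams(1.0, 0.3, SIGMA2_NU, 3.0, SIGMA2_ALPHA, 0.3, SIGMA2_TAU)
    ind = draw_individuals(pop, 6, rng)
    clean = generate_dataset(ind, 160, rng)
    return clean, contaminate(clean, ind, rng, rate=0.05), ind


class TestContamination:

    def test_exact_per_cell_count(self, contaminated):
        clean, dirty, _ = contaminated
        counts = (
            dirty.df[dirty.df["contaminant"] != "none"]
            .groupby(["participant", "condition"])
            .size()
        )
        assert len(counts) == 12
        assert (counts == 8).all()  # round(0.05 * 160)

    def test_untagged_trials_bit_identical(self, contaminated):
        clean, dirty, _ = contaminated
        keep = dirty.df["contaminant"] == "none"
        pd.testing.assert_frame_equal(
            clean.df[keep].reset_index(drop=True),
            dirty.df[keep].reset_index(drop=True),
        )

    def test_delayed_startups_shift_rt_keep_accuracy(self, contaminated):
        clean, dirty, _ = contaminated
        mask = dirty.df["contaminant"] == "delayed"
        offset = dirty.df.loc[mask, "rt"] - clean.df.loc[mask, "rt"]
        assert ((offset > 2) & (offset < 3)).all()
        assert (dirty.df.loc[mask, "accuracy"] == clean.df.loc[mask, "accuracy"]).all()

    def test_rate_zero_is_identity(self, contaminated):
        clean, _, ind = contaminated
        rng = np.random.default_rng(1)
        out = contaminate(clean, ind, rng, rate=0.0)
        pd.testing.assert_frame_equal(out.df, clean.df)

    def test_rate_bounds_and_double_contamination(self, contaminated):
        clean, dirty, ind = contaminated
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            contaminate(clean, ind, rng, rate=0.7)
        with pytest.raises(ValueError):
            contaminate(dirty, ind, rng, rate=0.05)

    def test_deterministic_given_seed(self, contaminated):
        clean, _, ind = contaminated
        a = contaminate(clean, ind, np.random.default_rng(3), rate=0.05)
        b = contaminate(clean, ind, np.random.default_rng(3), rate=0.05)
        pd.testing.assert_frame_equal(a.df, b.df)


def test_guess_trials_have_chance_accuracy():
    """Zero-drift redraws are correct about half the time."""
    rng = np.random.default_rng(13)
    pop = PopulationParams(2.5, 0.0, SIGMA2_NU, 3.0, SIGMA2_ALPHA, 0.3, SIGMA2_TAU)
    ind = draw_individuals(pop, 10, rng)
    clean = generate_dataset(ind, 320, rng)
    dirty = contaminate(clean, ind, rng, rate=0.5)
    guesses = dirty.df[dirty.df["contaminant"] == "guess"]
    n = len(guesses)
    assert n > 500
    assert abs(guesses["accuracy"].mean() - 0.5) < 3 * np.sqrt(0.25 / n)


def test_dataset_csv_roundtrip(tmp_path, small_dataset):
    from rezddm import Dataset

    _, _, data = small_dataset
    path = tmp_path / "data.csv"
    data.to_csv(path)
    back = Dataset.from_csv(path)
    pd.testing.assert_frame_equal(back.df, data.df)
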