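"""Scale-invariance of rank-based analyses; discordance of interactions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recipz import (
    DEFAULT_FLIP_CONFIG,
    FlipConfig,
    NULL_FLIP_CONFIG,
    NormativeStats,
    Scale,
    check_percentile_complement,
    demo_interaction_flip,
    interaction_term,
    percentile_rank,
    rank_test_equivalence,
)
from recipz.equivalence_props import gains_table
from recipz.synthetic_cohorts import PrePostDesign, PrePostSpec


class TestPercentiles:
    def test_formula_on_small_sample(self):
        sample = np.array([1.0, 2.0, 3.0])
        assert percentile_rank(1.0, sample) == pytest.approx(100 * 0.5 / 3)
        assert percentile_rank(2.0, sample) == pytest.approx(50.0)

    def test_ties_get_average_ranks(self):
        # hand enumeration on {1, 1, 2}: ranks 1.5, 1.5, 3
        sample = np.array([1.0, 1.0, 2.0])
        assert percentile_rank(1.0, sample) == pytest.approx(100 * 1.0 / 3)
        assert percentile_rank(2.0, sample) == pytest.approx(100 * 2.5 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            percentile_rank(1.0, np.array([]))

    @given(
        values=st.lists(
            st.floats(min_value=0.01, max_value=100), min_size=1, max_size=40
        )
    )
    def test_complement_identity(self, values):
        """p-th percentile on one scale = (100-p)-th on the reciprocal scale."""
        assert check_percentile_complement(np.array(values)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_complement_identity_with_ties(self):
        assert check_percentile_complement(np.array([1.0, 1.0, 2.0])) == 0.0

    def test_complement_at_study_scale(self, sim_config):
        rng = sim_config.rng(21)
        sample = 1.0 + 0.2 * rng.standard_normal(20_000)
        sample = sample[sample > 0]
        assert check_percentile_complement(sample) == pytest.approx(0.0, abs=1e-9)


class TestRankTests:
    def test_complete_separation(self):
        res = rank_test_equivalence([1.0, 2.0], [3.0, 4.0])
        assert res.u_raw == 0.0
        assert res.u_reciprocal == 4.0
        assert res.p_raw == res.p_reciprocal

    def test_identical_groups_give_p_one(self):
        res = rank_test_equivalence([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_raw == pytest.approx(1.0)
        assert res.p_reciprocal == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_reciprocal_preserves_p_and_complements_u(self, seed):
        """U flips to n_a*n_b - U under the reciprocal; p is untouched."""
        rng = np.random.default_rng(seed)
        a = np.abs(rng.normal(1.0, 0.3, size=rng.integers(5, 40)))
        b = np.abs(rng.normal(1.2, 0.3, size=rng.integers(5, 40)))
        res = rank_test_equivalence(a, b)
        assert res.u_reciprocal == pytest.approx(a.size * b.size - res.u_raw)
        assert abs(res.p_raw - res.p_reciprocal) < 1e-12

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_test_equivalence([], [1.0])


@given(
    y1=st.floats(min_value=0.05, max_value=50),
    gap=st.floats(min_value=0.001, max_value=10),
    offset=st.floats(min_value=0.001, max_value=50),
)
def test_equal_gaps_are_unequal_after_reciprocal(y1, gap, offset):
    """Strict convexity: the same raw gap shrinks on the reciprocal scale
    as the pair moves away from zero."""
    y2 = y1 + gap
    y3, y4 = y2 + offset, y2 + offset + gap
    assert (1 / y1 - 1 / y2) > (1 / y3 - 1 / y4)


def _toy_design(pre_a, post_a, pre_b, post_b) -> PrePostDesign:
    spec = PrePostSpec(
        stats=NormativeStats(scale=Scale.UNITS_PER_TIME, mean=1.0, sd=0.2),
        group_sizes=(len(pre_a), len(pre_b)),
    )
    return PrePostDesign(
        scale=Scale.UNITS_PER_TIME,
        groups=np.array(["A"] * len(pre_a) + ["B"] * len(pre_b)),
        pre=np.array(pre_a + pre_b),
        post=np.array(post_a + post_b),
        spec=spec,
    )


class TestInteractionTerm:
    def test_equal_gains_zero_on_generating_scale(self):
        design = _toy_design([0.2, 0.3], [0.4, 0.5], [0.8, 0.9], [1.0, 1.1])
        assert interaction_term(design, Scale.UNITS_PER_TIME) == pytest.approx(0.0)

    def test_nonzero_on_reciprocal_scale(self):
        """Equal rate-scale gains at distant baselines diverge in sec/syll."""
        design = _toy_design([0.2, 0.3], [0.4, 0.5], [0.8, 0.9], [1.0, 1.1])
        assert abs(interaction_term(design, Scale.TIME_PER_UNIT)) > 1.0

    def test_swapping_groups_negates(self):
        design = _toy_design([0.2, 0.3], [0.5, 0.4], [0.8, 0.9], [1.0, 1.1])
        swapped = PrePostDesign(
            scale=design.scale,
            groups=np.where(design.groups == "A", "B", "A"),
            pre=design.pre,
            post=design.post,
            spec=design.spec,
        )
        for scale in Scale:
            assert interaction_term(swapped, scale) == pytest.approx(
                -interaction_term(design, scale)
            )

    def test_gains_table_columns(self):
        df = gains_table(_toy_design([0.2, 0.3], [0.4, 0.5], [0.8, 0.9], [1.0, 1.1]))
        assert set(df.columns) == {
            "group",
            "gain_time_per_unit",
            "gain_units_per_time",
        }


class TestInteractionFlip:
    def test_default_config_flips_the_verdict(self):
        """Equal syll/sec gains, p ~ 1; the induced sec/syll interaction is
        highly significant — the scale choice decides the conclusion."""
        report = demo_interaction_flip(DEFAULT_FLIP_CONFIG)
        assert report["flipped"] is True
        assert report["p_value"][Scale.TIME_PER_UNIT.value] < 0.05
        assert report["p_value"][Scale.UNITS_PER_TIME.value] > 0.05

    def test_bit_reproducible_under_fixed_seed(self):
        r1 = demo_interaction_flip(DEFAULT_FLIP_CONFIG)
        r2 = demo_interaction_flip(DEFAULT_FLIP_CONFIG)
        assert r1["p_value"] == r2["p_value"]
        assert r1["interaction"] == r2["interaction"]

    def test_null_config_does_not_flip(self):
        report = demo_interaction_flip(NULL_FLIP_CONFIG)
        assert report["flipped"] is False
        assert min(report["p_value"].values()) > 0.05

    def test_zero_noise_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            demo_interaction_flip(FlipConfig(noise_sd_z=0.0))

    def test_more_noise_weakens_the_interaction(self):
        """Raising subject noise raises the sec/syll p-value (majority vote)."""
        wins = 0
        for seed in range(6):
            p_lo = demo_interaction_flip(
                FlipConfig(seed=seed, noise_sd_z=0.5, n_permutations=2_000)
            )["p_value"][Scale.TIME_PER_UNIT.value]
            p_hi = demo_interaction_flip(
                FlipConfig(seed=seed, noise_sd_z=4.0, n_permutations=2_000)
            )["p_value"][Scale.TIME_PER_UNIT.value]
            wins += p_hi >= p_lo
        assert wins >= 4
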