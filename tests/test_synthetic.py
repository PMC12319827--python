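"""Generator contracts: determinism, ranges, couplings, planted signal."""

import numpy as np
import pytest
from scipy import ndimage

from scpredict import (
    GeneratorConfig,
    make_cohort,
    make_parcellation,
    make_scalar_volumes,
    make_streamlines,
    plant_signal,
    simulate_connectomes,
)
from scpredict.containers import MAX_TRAIT_SCORE, TRAITS, score_items


class TestParcellation:
    def test_labels_cover_foreground_and_are_connected(self):
        vol = make_parcellation((10, 10, 10), 5, seed=1)
        labs = np.unique(vol.labels)
        assert set(labs) == {0, 1, 2, 3, 4, 5}
        assert (vol.roi_sizes() > 0).all()
        for r in range(1, 6):
            _, n_comp = ndimage.label(vol.labels == r)
            assert n_comp == 1, f"region {r} is disconnected"

    def test_single_region_takes_all_foreground(self):
        vol = make_parcellation((8, 8, 8), 1, seed=0)
        fg = vol.labels > 0
        assert fg.any()
        assert (vol.labels[fg] == 1).all()

    def test_deterministic(self):
        a = make_parcellation((9, 9, 9), 7, seed=5)
        b = make_parcellation((9, 9, 9), 7, seed=5)
        assert np.array_equal(a.labels, b.labels)
        c = make_parcellation((9, 9, 9), 7, seed=6)
        assert not np.array_equal(a.labels, c.labels)

    def test_too_many_regions_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            make_parcellation((3, 3, 3), 1000, seed=0)


class TestScalarVolumes:
    def test_ranges_and_negative_coupling(self):
        vol = make_parcellation((10, 10, 10), 4, seed=2)
        fa, md = make_scalar_volumes(vol, seed=2)
        assert fa.values.min() >= 0 and fa.values.max() <= 1
        assert md.values.min() > 0
        r = np.corrcoef(fa.values.ravel(), md.values.ravel())[0, 1]
        assert r < -0.5

    def test_deterministic(self):
        vol = make_parcellation((6, 6, 6), 3, seed=0)
        fa1, md1 = make_scalar_volumes(vol, seed=9)
        fa2, md2 = make_scalar_volumes(vol, seed=9)
        assert np.array_equal(fa1.values, fa2.values)
        assert np.array_equal(md1.values, md2.values)


class TestStreamlines:
    def test_count_length_and_labelled_endpoints(self):
        vol = make_parcellation((8, 8, 8), 4, seed=1)
        streams = make_streamlines(vol, 100, seed=4)
        assert len(streams) == 100
        for p in streams:
            assert p.shape[0] >= 2
            assert vol.labels[tuple(p[0])] > 0
            assert vol.labels[tuple(p[-1])] > 0

    def test_deterministic(self):
        vol = make_parcellation((8, 8, 8), 4, seed=1)
        a = make_streamlines(vol, 25, seed=7)
        b = make_streamlines(vol, 25, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestCohort:
    def test_scores_within_bounds_and_item_consistency(self):
        cohort = make_cohort(50, balanced_sex=True, seed=1)
        assert cohort.trait_scores.min() >= 0
        assert cohort.trait_scores.max() <= MAX_TRAIT_SCORE
        assert np.array_equal(score_items(cohort.item_responses), cohort.trait_scores)

    def test_balanced_cohort_has_equal_sexes(self):
        cohort = make_cohort(426, balanced_sex=True, seed=0)
        assert (cohort.sex == "F").sum() == 213
        assert (cohort.sex == "M").sum() == 213

    def test_all_max_items_reach_ceiling(self):
        items = np.full((1, 5, 12), 4)
        from scpredict.containers import REVERSED_ITEMS

        items[..., list(REVERSED_ITEMS)] = 0  # raw value whose reversal is 4
        assert (score_items(items) == 48).all()

    def test_odd_balanced_rejected(self):
        with pytest.raises(ValueError, match="even"):
            make_cohort(11, balanced_sex=True, seed=0)


class TestConnectomePopulation:
    def test_symmetry_zero_diagonal_and_ranges(self, small_benchmark):
        pop = small_benchmark.population
        for w in ("nos", "fa", "md"):
            mats = getattr(pop, w)
            assert np.array_equal(mats, mats.transpose(0, 2, 1))
            assert np.abs(np.diagonal(mats, axis1=1, axis2=2)).max() == 0
        assert (pop.nos >= 0).all()
        assert np.array_equal(pop.nos, np.rint(pop.nos))
        assert pop.fa.min() >= 0 and pop.fa.max() <= 1
        support = pop.nos > 0
        assert (pop.md[support] > 0).all()
        assert (pop.md[~support] == 0).all()

    def test_nos_marginal_right_skewed(self, small_benchmark):
        iu = np.triu_indices(10, 1)
        vals = small_benchmark.population.nos[:, iu[0], iu[1]].ravel()
        assert vals.mean() > np.median(vals)  # stretched toward large counts

    def test_fa_md_coupling_controls_correlation(self):
        cohort = make_cohort(100, balanced_sex=True, seed=2)
        cfg = GeneratorConfig(n_rois=30, n_subjects=100, fa_md_coupling=0.95, seed=2)
        pop = simulate_connectomes(cohort, 30, cfg)
        iu = np.triu_indices(30, 1)
        rs = [
            np.corrcoef(pop.fa[s][iu], pop.md[s][iu])[0, 1] for s in range(100)
        ]
        assert np.median(rs) > 0.8
        lo = simulate_connectomes(
            cohort, 30, GeneratorConfig(n_rois=30, n_subjects=100,
                                        fa_md_coupling=0.0, seed=2)
        )
        rs_lo = [
            np.corrcoef(lo.fa[s][iu], lo.md[s][iu])[0, 1] for s in range(100)
        ]
        assert np.median(rs_lo) < np.median(rs)

    def test_deterministic(self):
        cohort = make_cohort(20, balanced_sex=True, seed=5)
        cfg = GeneratorConfig(n_rois=8, n_subjects=20, seed=5)
        a = simulate_connectomes(cohort, 8, cfg)
        b = simulate_connectomes(cohort, 8, cfg)
        assert np.array_equal(a.nos, b.nos)
        assert np.array_equal(a.fa, b.fa)
        assert np.array_equal(a.md, b.md)


@pytest.fixture(scope="module")
def population():
    cohort = make_cohort(400, balanced_sex=True, seed=8)
    cfg = GeneratorConfig(n_rois=10, n_subjects=400, seed=8)
    return cohort, simulate_connectomes(cohort, 10, cfg)


class TestPlantSignal:

    def test_null_effect_gives_independent_target(self, population):
        cohort, pop = population
        edges = np.arange(10)
        new, s = plant_signal(pop, cohort, "O", edges, 0.0, seed=1, return_info=True)
        r = np.corrcoef(new.target("O"), s)[0, 1]
        assert abs(r) < 0.15

    def test_noiseless_undiscretized_target_is_exact(self, population):
        cohort, pop = population
        edges = np.arange(10)
        target, s = plant_signal(
            pop, cohort, "O", edges, 1.0, seed=1, discretize=False, return_info=True
        )
        assert np.corrcoef(target, s)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_effect_r2_recovered_across_seeds(self):
        """Sample R^2 of the target on the combination near the planted value."""
        hits = 0
        for seed in range(100):
            cohort = make_cohort(400, balanced_sex=True, seed=seed)
            cfg = GeneratorConfig(n_rois=10, n_subjects=400, seed=seed)
            pop = simulate_connectomes(cohort, 10, cfg)
            new, s = plant_signal(
                pop, cohort, "O", np.arange(10), 0.25, seed=seed, return_info=True
            )
            r2 = np.corrcoef(new.target("O"), s)[0, 1] ** 2
            hits += 0.15 <= r2 <= 0.35
        assert hits >= 95

    def test_population_r2_monotone_in_effect(self, population):
        cohort, pop = population
        r2s = []
        for effect in (0.0, 0.1, 0.25, 0.5):
            new, s = plant_signal(
                pop, cohort, "O", np.arange(10), effect, seed=3, return_info=True
            )
            r2s.append(np.corrcoef(new.target("O"), s)[0, 1] ** 2)
        assert all(b >= a - 0.02 for a, b in zip(r2s, r2s[1:]))

    def test_invalid_effect_rejected(self, population):
        cohort, pop = population
        with pytest.raises(ValueError):
            plant_signal(pop, cohort, "O", np.arange(3), 1.5, seed=0)
        with pytest.raises(ValueError):
            plant_signal(pop, cohort, "O", np.array([], dtype=int), 0.5, seed=0)

    def test_trait_targets_stay_integer_in_bounds(self, population):
        cohort, pop = population
        new = plant_signal(pop, cohort, "E", np.arange(5), 0.4, seed=2)
        y = new.target("E")
        assert np.array_equal(y, np.rint(y))
        assert y.min() >= 0 and y.max() <= MAX_TRAIT_SCORE
        # other traits untouched
        for t in TRAITS:
            if t != "E":
                assert np.array_equal(new.target(t), cohort.target(t))
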