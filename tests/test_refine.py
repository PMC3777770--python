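"""False-positive rules, fuzzy connectedness, delineation, assembly."""

import numpy as np
import pytest

from mslseg.core import (
    CSF, GM, LESION, WM, AtlasMaskSet, BinaryMask, LabelMap,
    connected_components,
)
from mslseg.refine import (
    FuzzyConfig, RefinementConfig, assemble_final_labels, compute_affinities,
    delineate_lesions, fuzzy_connectedness, propagate_strength,
    reclassify_choroid_plexus, reclassify_dgm, remove_cgm_lesions,
    remove_rim_lesions, remove_small_lesions, run_refinement,
)
from oracles import maxmin_strength_paths, maxmin_strength_threshold


def _labels(shape=(6, 6, 6), fill=WM):
    return LabelMap(np.full(shape, fill, dtype=np.int32))


def _mask(shape=(6, 6, 6), value=False):
    return BinaryMask(np.full(shape, value))


class TestVetoRules:
    def test_cgm_rule_reclassifies_only_inside_mask(self):
        lab = _labels()
        lab.labels[1, 1, 1] = LESION
        lab.labels[4, 4, 4] = LESION
        cgm = _mask()
        cgm.mask[1, 1, 1] = True
        out = remove_cgm_lesions(lab, cgm)
        assert out.labels[1, 1, 1] == GM
        assert out.labels[4, 4, 4] == LESION
        # conservation: only lesion -> GM transitions
        changed = out.labels != lab.labels
        assert np.all(lab.labels[changed] == LESION)
        assert np.all(out.labels[changed] == GM)

    def test_rim_rule(self):
        lab = _labels((7, 7, 7))
        brain = _mask((7, 7, 7), True)
        lab.labels[0, 3, 3] = LESION      # on the brain surface
        lab.labels[3, 3, 3] = LESION      # deep
        out = remove_rim_lesions(lab, brain, rim_depth=2)
        assert out.labels[0, 3, 3] == GM
        assert out.labels[3, 3, 3] == LESION
        # rim_depth=0 is the identity
        np.testing.assert_array_equal(
            remove_rim_lesions(lab, brain, 0).labels, lab.labels)

    def test_rim_rule_eroding_everything_errors(self):
        lab = _labels((4, 4, 4))
        with pytest.raises(ValueError, match="erode"):
            remove_rim_lesions(lab, _mask((4, 4, 4), True), rim_depth=4)

    def test_small_component_rule(self):
        lab = _labels((12, 6, 6), fill=WM)
        lab.labels[0, 0, 0:2] = LESION                 # size 2
        lab.labels[3, 3, 0:3] = LESION                 # size 3
        lab.labels[6:8, 0, 0:2] = LESION               # size 4
        out = remove_small_lesions(lab, min_voxels=3, connectivity=26)
        lesions = BinaryMask(out.labels == LESION)
        comp = connected_components(lesions, 26)
        assert comp.n_components == 1 and comp.sizes[0] == 4
        assert np.all(comp.sizes > 3)
        np.testing.assert_array_equal(
            remove_small_lesions(lab, 0).labels, lab.labels)  # identity at 0

    def test_choroid_rule_touches_lesions_only(self):
        lab = _labels()
        lab.labels[2, 2, 2] = LESION      # inside lvc
        lab.labels[5, 5, 5] = LESION      # outside
        lab.labels[2, 2, 3] = CSF
        lvc = _mask()
        lvc.mask[2, 2, 2] = True
        out = reclassify_choroid_plexus(lab, lvc, lvc_dilate=0)
        assert out.labels[2, 2, 2] == CSF
        assert out.labels[5, 5, 5] == LESION
        changed = out.labels != lab.labels
        assert np.all(lab.labels[changed] == LESION)

    def test_choroid_rule_dilates_zone(self):
        lab = _labels()
        lab.labels[2, 2, 3] = LESION      # one voxel outside the raw lvc
        lvc = _mask()
        lvc.mask[2, 2, 2] = True
        assert reclassify_choroid_plexus(lab, lvc, 1).labels[2, 2, 3] == CSF

    def test_dgm_rule(self):
        lab = _labels()
        lab.labels[1, 1, 1] = WM
        lab.labels[1, 1, 2] = GM
        lab.labels[1, 1, 3] = LESION
        dgm = _mask()
        dgm.mask[1, 1, 1:4] = True
        out = reclassify_dgm(lab, dgm)
        assert out.labels[1, 1, 1] == GM
        assert out.labels[1, 1, 2] == GM
        assert out.labels[1, 1, 3] == LESION   # kept by default
        out2 = reclassify_dgm(lab, dgm, include_lesions=True)
        assert out2.labels[1, 1, 3] == GM


class TestFuzzyConnectedness:
    def test_strength_is_one_at_seeds(self, rng):
        grid = rng.random((5, 5, 5)) * 100
        seeds = np.zeros((5, 5, 5), dtype=bool)
        seeds[2, 2, 2] = True
        mask = np.ones((5, 5, 5), dtype=bool)
        cmap = fuzzy_connectedness(grid, BinaryMask(seeds), BinaryMask(mask))
        assert cmap.strength[2, 2, 2] == 1.0
        assert cmap.strength.max() <= 1.0

    def test_chain_strength_is_path_minimum(self):
        # 1x1x4 chain with face affinities 0.9, 0.5, 0.8 from a seed at one end
        affs = [np.zeros((0, 1, 4)), np.zeros((1, 0, 4)),
                np.array([[[0.9, 0.5, 0.8]]])]
        seeds = np.zeros((1, 1, 4), dtype=bool)
        seeds[0, 0, 0] = True
        mask = np.ones((1, 1, 4), dtype=bool)
        s = propagate_strength(affs, seeds, mask)
        np.testing.assert_allclose(s[0, 0], [1.0, 0.9, 0.5, 0.5])

    def test_matches_exhaustive_path_enumeration_tiny(self, rng):
        shape = (2, 2, 2)
        affs = [rng.random((1, 2, 2)), rng.random((2, 1, 2)), rng.random((2, 2, 1))]
        seeds = np.zeros(shape, dtype=bool)
        seeds[0, 0, 0] = True
        mask = np.ones(shape, dtype=bool)
        got = propagate_strength(affs, seeds, mask)
        np.testing.assert_allclose(got, maxmin_strength_paths(affs, seeds, mask),
                                   atol=1e-12)

    def test_matches_threshold_oracle_with_mask_holes(self, rng):
        shape = (4, 4, 4)
        affs = [rng.random((3, 4, 4)), rng.random((4, 3, 4)), rng.random((4, 4, 3))]
        mask = rng.random(shape) < 0.85
        mask[0, 0, 0] = True
        seeds = np.zeros(shape, dtype=bool)
        seeds[0, 0, 0] = True
        for a in range(3):
            hi = [slice(None)] * 3
            lo = [slice(None)] * 3
            hi[a], lo[a] = slice(1, None), slice(0, -1)
            affs[a][~(mask[tuple(lo)] & mask[tuple(hi)])] = 0.0
        got = propagate_strength(affs, seeds, mask)
        np.testing.assert_allclose(got, maxmin_strength_threshold(affs, seeds, mask),
                                   atol=1e-12)

    def test_empty_seed_set_errors(self, rng):
        grid = rng.random((4, 4, 4))
        with pytest.raises(ValueError, match="seed"):
            fuzzy_connectedness(grid, BinaryMask(np.zeros((4, 4, 4), dtype=bool)),
                                BinaryMask(np.ones((4, 4, 4), dtype=bool)))

    def test_affinity_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FuzzyConfig(w1=0.7, w2=0.5)


class TestDelineation:
    def _setup(self, rng):
        shape = (8, 8, 8)
        grid = np.full(shape, 70.0)
        grid[3:6, 3:6, 3:6] = 150.0          # lesion-bright blob
        labels = LabelMap(np.full(shape, WM, dtype=np.int32))
        labels.labels[4, 4, 4] = LESION       # under-segmented seed
        atlas = AtlasMaskSet(_mask(shape), _mask(shape), _mask(shape), _mask(shape))
        brain = _mask(shape, True)
        return grid, labels, atlas, brain

    def test_growth_is_monotone_in_theta(self, rng):
        grid, labels, atlas, brain = self._setup(rng)
        seeds = BinaryMask(labels.labels == LESION)
        cmap = fuzzy_connectedness(grid, seeds, brain, FuzzyConfig(s=10.0, s_g=10.0))
        rules = RefinementConfig(rim_depth=0)
        sets = []
        for theta in (0.3, 0.6, 0.9):
            out = delineate_lesions(labels, cmap, theta, atlas, brain, rules)
            sets.append(out.labels == LESION)
        assert np.all(sets[2] <= sets[1]) and np.all(sets[1] <= sets[0])
        for s in sets:
            assert np.all(s[labels.labels == LESION])  # growth only adds

    def test_theta_one_keeps_only_strength_one(self, rng):
        grid, labels, atlas, brain = self._setup(rng)
        seeds = BinaryMask(labels.labels == LESION)
        cmap = fuzzy_connectedness(grid, seeds, brain, FuzzyConfig(s=10.0, s_g=10.0))
        out = delineate_lesions(labels, cmap, 1.0, atlas, brain,
                                RefinementConfig(rim_depth=0))
        grown = (out.labels == LESION) & ~seeds.mask
        assert np.all(cmap.strength[grown] >= 1.0)

    def test_exclusion_zones_respected(self, rng):
        grid, labels, atlas, brain = self._setup(rng)
        atlas.cgm.mask[3, :, :] = True
        seeds = BinaryMask(labels.labels == LESION)
        cmap = fuzzy_connectedness(grid, seeds, brain, FuzzyConfig(s=10.0, s_g=10.0))
        out = delineate_lesions(labels, cmap, 0.3, atlas, brain,
                                RefinementConfig(rim_depth=0))
        grown = (out.labels == LESION) & ~seeds.mask
        assert not np.any(grown[3, :, :])

    def test_invalid_theta(self, rng):
        grid, labels, atlas, brain = self._setup(rng)
        seeds = BinaryMask(labels.labels == LESION)
        cmap = fuzzy_connectedness(grid, seeds, brain, FuzzyConfig(s=10.0, s_g=10.0))
        with pytest.raises(ValueError, match="theta"):
            delineate_lesions(labels, cmap, 0.0, atlas, brain, RefinementConfig())


class TestAssembly:
    def test_override_order(self):
        shape = (4, 4, 4)
        cerebral = LabelMap(np.full(shape, WM, dtype=np.int32))
        cereb_mask = _mask(shape)
        cereb_mask.mask[0] = True
        cerebellar = LabelMap(np.where(cereb_mask.mask, GM, 0).astype(np.int32))
        lesions = _mask(shape)
        lesions.mask[2, 2, 2] = True
        out = assemble_final_labels(cerebral, cerebellar, lesions, cereb_mask)
        assert out.labels[2, 2, 2] == LESION
        assert np.all(out.labels[0] == GM)
        assert out.labels[1, 0, 0] == WM

    def test_empty_lesions_is_union_of_tissue_maps(self):
        shape = (4, 4, 4)
        cerebral = LabelMap(np.full(shape, CSF, dtype=np.int32))
        out = assemble_final_labels(cerebral,
                                    LabelMap(np.zeros(shape, dtype=np.int32)),
                                    _mask(shape), _mask(shape))
        np.testing.assert_array_equal(out.labels, cerebral.labels)

    def test_cerebellar_labels_outside_mask_error(self):
        shape = (4, 4, 4)
        cerebral = LabelMap(np.full(shape, WM, dtype=np.int32))
        cerebellar = LabelMap(np.full(shape, GM, dtype=np.int32))
        with pytest.raises(ValueError, match="cerebellum"):
            assemble_final_labels(cerebral, cerebellar, _mask(shape), _mask(shape))


def test_cascade_is_idempotent_on_phantom(phantom, pipeline_result):
    res = pipeline_result
    again = run_refinement(res.final_labels,
                           res.std_volume.channels["flair"],
                           phantom.atlas, res.brain_mask)
    np.testing.assert_array_equal(again.labels, res.final_labels.labels)
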