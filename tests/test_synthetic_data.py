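"""Phantom geometry, perturbation contracts, voxelization, forward model."""

import numpy as np
import pytest
from scipy import stats

from striocomp.io_core import VolumeGrid
from striocomp.parcellation import Label, classify, compute_probability
from striocomp.synthetic_data import (
    ForwardModel,
    PerturbationError,
    PerturbationSpec,
    PhantomParams,
    TissuePhantom,
    apply_perturbation,
    fractions_to_counts,
    generate_phantom,
    simulate_cohort,
    split_nuclei,
    voxelize,
)
from striocomp.cohort_stats import age_window_months


@pytest.fixture(scope="module")
def phantom():
    return generate_phantom(seed=42)


def label_centroid(phantom, label):
    idx = np.argwhere(phantom.labels.data == label)
    return phantom.labels.voxel_centers_mm(idx).mean(axis=0)


class TestGeneratePhantom:
    def test_volume_fraction_within_tolerance(self, phantom):
        target = phantom.params.striosome_fraction
        assert abs(phantom.striosome_fraction - target) <= 0.10 * target + 1e-9

    def test_at_least_twenty_branches(self, phantom):
        assert len(phantom.branches) >= 20

    def test_tubule_diameters_within_configured_range(self, phantom):
        lo, hi = phantom.params.diameter_range_mm
        for branch in phantom.branches:
            assert lo / 2 <= branch.radius_mm <= hi / 2

    def test_striosome_interior_to_envelope(self, phantom):
        # no striosome voxel may touch the exterior across a face
        labels = phantom.labels.data
        strio = labels == TissuePhantom.STRIOSOME
        ext = labels == TissuePhantom.EXTERIOR
        for axis in range(3):
            for shift in (1, -1):
                assert not (strio & np.roll(ext, shift, axis=axis)).any()

    def test_gradient_enriches_medial_rostral_ventral(self, phantom):
        strio = label_centroid(phantom, TissuePhantom.STRIOSOME)
        matrix = label_centroid(phantom, TissuePhantom.MATRIX)
        assert strio[0] < matrix[0]  # more medial (-x)
        assert strio[1] > matrix[1]  # more rostral (+y)
        assert strio[2] < matrix[2]  # more ventral (-z)

    def test_zero_gradient_is_centered(self):
        params = PhantomParams(gradient_weights=(0.0, 0.0, 0.0))
        ph = generate_phantom(params, seed=7)
        centroid = label_centroid(ph, TissuePhantom.STRIOSOME)
        # isotropy: centroid close to envelope center relative to semi-axes
        rel = np.abs(centroid) / np.array(params.envelope_semi_axes_mm)
        assert (rel < 0.12).all()


class TestPerturbations:
    def test_scenario_c_leaves_striosome_bit_identical(self, phantom):
        pert = apply_perturbation(phantom, PerturbationSpec("C", 0.1, seed=1))
        strio_before = phantom.labels.data == TissuePhantom.STRIOSOME
        strio_after = pert.labels.data == TissuePhantom.STRIOSOME
        np.testing.assert_array_equal(strio_before, strio_after)
        growth = pert.matrix_voxels / phantom.matrix_voxels - 1
        assert growth == pytest.approx(0.1, abs=0.02)

    def test_scenario_a_halves_volume_with_thickness_unchanged(self, phantom):
        pert = apply_perturbation(phantom, PerturbationSpec("A", 0.5, seed=2))
        ratio = pert.striosome_voxels / phantom.striosome_voxels
        assert ratio == pytest.approx(0.5, abs=0.08)
        radii_before = [b.radius_mm for b in phantom.branches]
        radii_after = [b.radius_mm for b in pert.branches]
        assert len(radii_after) < len(radii_before)
        # deleted at random: thickness distribution statistically unchanged
        ks = stats.ks_2samp(radii_before, radii_after)
        assert ks.pvalue > 0.05

    def test_scenario_b_conserves_volume_with_fewer_branches(self, phantom):
        pert = apply_perturbation(phantom, PerturbationSpec("B", 0.3, seed=3))
        assert pert.striosome_voxels == pytest.approx(
            phantom.striosome_voxels, rel=0.02
        )
        assert len(pert.branches) < len(phantom.branches)
        mean_r_before = np.mean([b.radius_mm for b in phantom.branches])
        mean_r_after = np.mean([b.radius_mm for b in pert.branches])
        assert mean_r_after > mean_r_before  # thicker tubes

    def test_scenario_b_inflation_beyond_cap_is_an_error(self, phantom):
        from dataclasses import replace

        tight = replace(phantom, params=replace(phantom.params,
                                                max_inflated_diameter_mm=1.3))
        with pytest.raises(PerturbationError, match="exceeds"):
            apply_perturbation(tight, PerturbationSpec("B", 0.4, seed=4))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            PerturbationSpec("D", 0.2)
        with pytest.raises(ValueError, match="magnitude"):
            PerturbationSpec("A", 0.9)


class TestVoxelize:
    def test_volume_conserved_within_one_percent(self, phantom):
        fmap = voxelize(phantom)
        k = int(round(phantom.params.voxel_mm / phantom.params.highres_mm))
        highres_strio = phantom.striosome_voxels
        coarse_strio = (
            fmap.f.data * fmap.tissue_fraction.data * k**3
        ).sum()
        assert coarse_strio == pytest.approx(highres_strio, rel=0.01)

    def test_pure_matrix_voxel_has_zero_fraction(self, phantom):
        fmap = voxelize(phantom)
        inside = fmap.striatum.grid.data
        assert fmap.f.data[inside].min() == 0.0

    def test_hand_built_block_ratio(self):
        # 8x8x8 high-res block with 64 striosome voxels of 512 -> f = 0.125
        params = PhantomParams()
        label = np.full((8, 8, 8), TissuePhantom.MATRIX, dtype=np.uint8)
        label[:4, :4, :4] = TissuePhantom.STRIOSOME
        grid = VolumeGrid(label, voxel_size_mm=(0.25,) * 3)
        ph = TissuePhantom(labels=grid, branches=[], params=params)
        fmap = voxelize(ph)
        assert fmap.f.data.shape == (1, 1, 1)
        assert fmap.f.data[0, 0, 0] == pytest.approx(64 / 512)

    def test_non_integer_ratio_rejected(self, phantom):
        with pytest.raises(ValueError, match="integer multiple"):
            voxelize(phantom, voxel_mm=0.9)

    def test_exterior_dominated_voxels_masked_out(self, phantom):
        fmap = voxelize(phantom)
        outside = ~fmap.striatum.grid.data
        assert (fmap.tissue_fraction.data[outside] <= 0.5).all()


class TestForwardModel:
    def test_strictly_decreasing_in_fraction(self):
        model = ForwardModel()
        f = np.linspace(0, 1, 101)
        p = model.p_matrix(f)
        assert (np.diff(p) < 0).all()

    def test_midpoint_maps_to_half(self):
        model = ForwardModel()
        assert model.p_matrix(model.midpoint) == pytest.approx(0.5)

    def test_pure_matrix_reaches_ceiling(self):
        assert ForwardModel().p_matrix(0.0) >= 0.95

    def test_increasing_mapping_rejected(self):
        with pytest.raises(ValueError, match="steepness"):
            ForwardModel(steepness=-3)

    def test_midpoint_voxels_classify_indeterminate_noise_free(self, config):
        model = ForwardModel(noise_sigma=0.0)
        n = 16
        f = np.full((n, 1, 1), model.midpoint)
        from striocomp.io_core import RegionMask

        geometry = dict(voxel_size_mm=(2.0,) * 3)
        from striocomp.synthetic_data import FractionMap

        fmap = FractionMap(
            f=VolumeGrid(f, **geometry),
            striatum=RegionMask(
                VolumeGrid(np.ones((n, 1, 1), dtype=bool), **geometry), "striatum"
            ),
            tissue_fraction=VolumeGrid(np.ones((n, 1, 1)), **geometry),
        )
        counts = fractions_to_counts(fmap, model, seed=0)
        parc = classify(compute_probability(counts), config)
        assert parc.count(Label.INDETERMINATE) == n

    def test_monte_carlo_ratio_recovers_probability(self):
        """Mean recovered p over 10^4 noisy draws within +/-0.01 of model p."""
        from striocomp.io_core import RegionMask
        from striocomp.synthetic_data import FractionMap

        model = ForwardModel()
        n = 10_000
        f_true = 0.3
        geometry = dict(voxel_size_mm=(2.0,) * 3)
        fmap = FractionMap(
            f=VolumeGrid(np.full((n, 1, 1), f_true), **geometry),
            striatum=RegionMask(
                VolumeGrid(np.ones((n, 1, 1), dtype=bool), **geometry), "striatum"
            ),
            tissue_fraction=VolumeGrid(np.ones((n, 1, 1)), **geometry),
        )
        counts = fractions_to_counts(fmap, model, seed=9)
        pmap = compute_probability(counts)
        recovered = pmap.p_matrix.data[pmap.defined_mask].mean()
        assert recovered == pytest.approx(float(model.p_matrix(f_true)), abs=0.01)


class TestCohortSimulation:
    def test_split_nuclei_partitions_striatum(self, phantom):
        fmap = voxelize(phantom)
        caudate, putamen = split_nuclei(fmap.striatum)
        assert not (caudate.grid.data & putamen.grid.data).any()
        assert (
            (caudate.grid.data | putamen.grid.data) == fmap.striatum.grid.data
        ).all()

    def test_cohort_structure_and_demographics(self):
        cohort = simulate_cohort(3, scenario="C", magnitude=0.2, seed=5)
        assert len(cohort.pairs) == 3
        for case, control in cohort.pairs:
            assert case.record.is_case
            assert not control.record.is_case
            assert case.record.sex == control.record.sex
            gap = abs(case.record.age_months - control.record.age_months)
            assert gap <= age_window_months(case.record.age_months)
        assert cohort.demographics.shape[0] == 3

    def test_case_streamline_deficit_applied(self):
        cohort = simulate_cohort(3, scenario=None, seed=6,
                                 case_streamline_deficit=0.10)
        case_tot = np.mean(
            [c.waytotal_bait_matrix + c.waytotal_bait_striosome for c in cohort.cases]
        )
        ctrl_tot = np.mean(
            [c.waytotal_bait_matrix + c.waytotal_bait_striosome
             for c in cohort.controls]
        )
        assert case_tot / ctrl_tot == pytest.approx(0.90, abs=0.03)

    def test_fa_gap_recovered_from_masks(self, config):
        """Injected +4% matrix-side FA is recovered via equal-volume masks."""
        from striocomp.connectivity_metrics import scalar_by_compartment
        from striocomp.masks_geometry import build_equal_volume_masks

        cohort = simulate_cohort(8, scenario=None, seed=11, fa_gap=0.04)
        diffs = []
        for subj in cohort.controls:
            masks = build_equal_volume_masks(subj.pmap, config)
            summary = scalar_by_compartment(subj.fa_map, masks, subj.record.subject_id)
            diffs.append(summary.percent_difference)
        # pure matrix vs mixed striosome-like voxels: positive gap, below 4%
        assert np.mean(diffs) > 1.0
        assert np.mean(diffs) < 5.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="n_pairs"):
            simulate_cohort(1)
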