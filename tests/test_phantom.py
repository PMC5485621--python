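"""Phantom generator: geometry, intensities, PTV placement, perturbation."""

import dataclasses

import numpy as np
import pytest

import synctplan.tissues as T
from synctplan.phantom import (
    PTV_SIZE_CLASSES,
    PhantomSpec,
    PTVPlacementError,
    build_phantom,
    perturb_geometry,
    simulate_dixon,
)

from conftest import small_spec


class TestBuildPhantom:
    def test_every_voxel_labelled(self, noiseless_phantom):
        labels, _, _ = noiseless_phantom
        assert np.isin(labels.values, list(T.LABEL_NAMES)).all()

    def test_zero_noise_ct_is_piecewise_constant(self, noiseless_phantom):
        labels, ct, _ = noiseless_phantom
        for code in (T.AIR, T.FAT, T.LUNG, T.SOFT_TISSUE):
            vals = np.unique(ct.values[labels.values == code])
            assert vals.size == 1 and vals[0] == T.CLASS_HU[code]
        bone = ct.values[labels.values == T.BONE]
        assert bone.min() >= T.HU_BONE_MIN - 1e-9
        assert bone.max() <= T.HU_BONE_MAX + 1e-9

    def test_ptv_volume_within_one_voxel_of_target(self, noiseless_spec,
                                                   noiseless_phantom):
        _, _, structures = noiseless_phantom
        voxvol = np.prod(noiseless_spec.spacing) / 1000.0
        vol = structures.array("PTV").sum() * voxvol
        assert abs(vol - 11.9) <= voxvol

    def test_ptv_inside_lung(self, noiseless_phantom):
        labels, _, st = noiseless_phantom
        ptv = st.array("PTV")
        lung = st.array("lung_left") | st.array("lung_right")
        assert (ptv & ~lung).sum() == 0
        # PTV voxels keep the lung label until the planning-time override
        assert (labels.values[ptv] == T.LUNG).all()

    def test_masks_consistent_with_labels(self, noiseless_phantom):
        labels, _, st = noiseless_phantom
        assert (labels.values[st.array("spine")] == T.BONE).all()
        assert (labels.values[st.array("lung_left")] == T.LUNG).all()
        assert (labels.values[st.array("spinal_cord")] == T.SOFT_TISSUE).all()

    def test_determinism_under_fixed_seed(self):
        spec = small_spec(hu_noise_sd=15.0, seed=21)
        l1, c1, s1 = build_phantom(spec)
        l2, c2, s2 = build_phantom(spec)
        assert np.array_equal(l1.values, l2.values)
        assert np.array_equal(c1.values, c2.values)
        for name in s1.names:
            assert np.array_equal(s1.array(name), s2.array(name))

    @pytest.mark.parametrize("size_class", ["small", "medium", "large"])
    def test_drawn_volumes_within_two_sd_of_class(self, size_class):
        mean, sd = PTV_SIZE_CLASSES[size_class]
        for seed in (1, 2, 3):
            spec = small_spec(ptv_size_class=size_class, ptv_volume_cm3=None,
                              seed=seed)
            _, _, st = build_phantom(spec)
            vol = st.array("PTV").sum() * np.prod(spec.spacing) / 1000.0
            assert mean - 2 * sd <= vol <= mean + 2 * sd

    def test_impossible_ptv_raises_placement_error(self):
        spec = small_spec(ptv_volume_cm3=2000.0)
        with pytest.raises(PTVPlacementError, match="lung"):
            build_phantom(spec)

    def test_lung_hu_offset_shifts_lung_only(self):
        spec = small_spec(lung_hu_offset=30.0)
        labels, ct, _ = build_phantom(spec)
        assert np.unique(ct.values[labels.values == T.LUNG]) == T.HU_LUNG + 30.0
        assert np.unique(ct.values[labels.values == T.SOFT_TISSUE]) == T.HU_SOFT


class TestSimulateDixon:
    def test_signal_table_contrasts(self, noiseless_phantom, noiseless_spec,
                                    noiseless_dixon):
        labels, _, _ = noiseless_phantom
        d = noiseless_dixon
        fat = labels.values == T.FAT
        assert (d.fat.values[fat] > d.water.values[fat]).all()
        soft = labels.values == T.SOFT_TISSUE
        assert (d.water.values[soft] > d.fat.values[soft]).all()
        air = labels.values == T.AIR
        assert (d.water.values[air] == 0).all() and (d.fat.values[air] == 0).all()

    def test_coarser_mr_grid(self, noiseless_phantom):
        labels, _, _ = noiseless_phantom
        spec = small_spec(mr_spacing=(6.0, 6.0, 7.5))
        d = simulate_dixon(labels, spec)
        assert d.grid.spacing == (6.0, 6.0, 7.5)
        # world extent preserved within a voxel
        for ax in range(3):
            assert (
                abs(d.grid.shape[ax] * d.grid.spacing[ax]
                    - labels.grid.shape[ax] * labels.grid.spacing[ax])
                <= d.grid.spacing[ax]
            )


class TestPerturbGeometry:
    def test_zero_magnitude_is_identity(self, noiseless_phantom):
        _, ct, _ = noiseless_phantom
        out, field = perturb_geometry(ct, 0.0, seed=3)
        assert np.array_equal(out.values, ct.values)
        assert np.abs(field).max() == 0

    @pytest.mark.parametrize("magnitude", [2.0, 5.0])
    def test_max_norm_bounded(self, noiseless_phantom, magnitude):
        _, ct, _ = noiseless_phantom
        _, field = perturb_geometry(ct, magnitude, seed=5)
        norms = np.sqrt((field**2).sum(axis=0))
        assert norms.max() <= magnitude + 1e-9
        assert norms.max() > 0.5 * magnitude  # scaled to hit the bound

    def test_seeded_determinism(self, noiseless_phantom):
        _, ct, _ = noiseless_phantom
        v1, f1 = perturb_geometry(ct, 4.0, seed=9)
        v2, f2 = perturb_geometry(ct, 4.0, seed=9)
        assert np.array_equal(v1.values, v2.values)
        assert np.array_equal(f1, f2)

    def test_negative_magnitude_rejected(self, noiseless_phantom):
        _, ct, _ = noiseless_phantom
        with pytest.raises(ValueError):
            perturb_geometry(ct, -1.0, seed=0)


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(spacing=(0.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        PhantomSpec(ptv_size_class="gigantic")
    with pytest.raises(ValueError):
        PhantomSpec(ptv_location_class="nowhere")


def test_anatomy_variants_are_affine_and_deterministic():
    from synctplan.phantom import patient_spec_variants

    base = small_spec()
    a = patient_spec_variants(base, 3, seed=5)
    b = patient_spec_variants(base, 3, seed=5)
    assert [dataclasses.asdict(x) for x in a] == [dataclasses.asdict(x) for x in b]
    assert len({x.seed for x in a}) == 3
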