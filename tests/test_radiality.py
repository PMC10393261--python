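import numpy as np
import pytest

from synapsekit import (
    ChannelImage,
    OrientationField,
    SyntheticCellSpec,
    degree_of_radiality,
    dor_at,
    dor_profile,
    fit_hull_efd,
    make_filament_cell,
    orientation_field,
    radial_circular_fields,
    radial_sections,
)
from synapsekit.segmentation import mask_to_cell
from synapsekit.synthetic import make_rough_mask


class TestOrientationField:
    @pytest.mark.parametrize("deg", [0, 30, 60, 120])
    def test_stripe_angle_recovered(self, stripe_image, square_cell, deg):
        theta = np.deg2rad(deg)
        field = orientation_field(stripe_image(theta), square_cell, sigma_px=1.5)
        interior = np.zeros(square_cell.shape, dtype=bool)
        interior[20:76, 20:76] = True
        diff = np.abs(field.angle[interior] - theta)
        diff = np.minimum(diff, np.pi - diff)
        assert diff.max() < 0.05

    def test_constant_image_no_coherence(self, square_cell):
        img = ChannelImage(np.full((96, 96), 50.0), 0.1)
        field = orientation_field(img, square_cell, sigma_px=1.5, coherence_min=0.1)
        assert (field.coherence == 0).all()
        assert not field.valid.any()

    def test_coherence_bounded_and_high_on_stripes(self, stripe_image, square_cell):
        field = orientation_field(stripe_image(0.5), square_cell)
        assert field.coherence.min() >= 0 and field.coherence.max() <= 1 + 1e-9
        assert np.median(field.coherence[square_cell.mask]) > 0.9

    def test_valid_restricted_to_hull(self, stripe_image, square_cell):
        field = orientation_field(stripe_image(0.3), square_cell)
        assert not (field.valid & ~square_cell.hull).any()

    def test_bad_parameters_rejected(self, stripe_image, square_cell):
        with pytest.raises(ValueError, match="sigma"):
            orientation_field(stripe_image(0.0), square_cell, sigma_px=0.0)
        with pytest.raises(ValueError, match="coherence"):
            orientation_field(stripe_image(0.0), square_cell, coherence_min=1.0)


class TestRadialSections:
    def test_disk_annulus_areas(self, disk_cell):
        """K=4 sections of a disk are annuli with area ratios 1:3:5:7."""
        efd = fit_hull_efd(disk_cell, 10)
        sec = radial_sections(efd, disk_cell.center_of_mass, K=4, hull=disk_cell.hull)
        counts = np.array([(sec.section_index == k).sum() for k in range(1, 5)])
        ratios = counts / counts[0]
        np.testing.assert_allclose(ratios, [1, 3, 5, 7], rtol=0.10)

    def test_partition_covers_hull_minus_center(self):
        cell = mask_to_cell(make_rough_mask((40.0, 28.0)))
        efd = fit_hull_efd(cell, 10)
        sec = radial_sections(efd, cell.center_of_mass, K=4, hull=cell.hull)
        rr, cc = np.meshgrid(*map(np.arange, cell.shape), indexing="ij")
        dist = np.hypot(rr - cell.center_of_mass[0], cc - cell.center_of_mass[1])
        expected = cell.hull & (dist > 1.0)
        assert ((sec.section_index > 0) == expected).all()

    def test_sections_nondecreasing_along_rays(self, disk_cell):
        efd = fit_hull_efd(disk_cell, 10)
        sec = radial_sections(efd, disk_cell.center_of_mass, K=4, hull=disk_cell.hull)
        r0, c0 = (int(round(x)) for x in disk_cell.center_of_mass)
        for dr, dc in [(0, 1), (1, 0), (1, 1), (-1, 1)]:
            ray = []
            r, c = r0 + dr, c0 + dc
            while disk_cell.hull[r, c]:
                if sec.section_index[r, c] > 0:
                    ray.append(sec.section_index[r, c])
                r, c = r + dr, c + dc
            assert ray == sorted(ray)

    def test_relative_distance_labels(self, disk_cell):
        efd = fit_hull_efd(disk_cell, 10)
        sec = radial_sections(efd, disk_cell.center_of_mass, K=6, hull=disk_cell.hull)
        np.testing.assert_array_equal(sec.relative_distance, np.arange(1.0, 7.0))

    def test_k_too_small_rejected(self, disk_cell):
        efd = fit_hull_efd(disk_cell, 10)
        with pytest.raises(ValueError, match="K"):
            radial_sections(efd, disk_cell.center_of_mass, K=1)


def _synthetic_field(cell, offset_rad):
    """Orientation field whose angle is radial + offset at every hull pixel."""
    r0, c0 = cell.center_of_mass
    rr, cc = np.meshgrid(*map(np.arange, cell.shape), indexing="ij")
    radial_angle = np.arctan2(rr - r0, cc - c0)
    angle = np.mod(radial_angle + offset_rad, np.pi)
    return OrientationField(angle=angle, coherence=np.ones(cell.shape),
                            valid=cell.hull.copy())


def _dor_inputs(cell, K=4):
    radial, circular = radial_circular_fields(cell)
    efd = fit_hull_efd(cell, 10)
    sections = radial_sections(efd, cell.center_of_mass, K=K, hull=cell.hull)
    return radial, circular, sections


class TestDegreeOfRadiality:
    def test_pure_radial_hits_epsilon_guard(self, disk_cell):
        radial, circular, sections = _dor_inputs(disk_cell)
        field = _synthetic_field(disk_cell, 0.0)
        prof = degree_of_radiality(field, radial, circular, sections, epsilon=1e-6)
        n = prof.n_pixels.astype(float)
        # numerator = N per section, denominator clipped to epsilon
        np.testing.assert_allclose(prof.dor, n / 1e-6, rtol=1e-6)

    def test_pure_tangential_is_zero(self, disk_cell):
        radial, circular, sections = _dor_inputs(disk_cell)
        field = _synthetic_field(disk_cell, np.pi / 2)
        prof = degree_of_radiality(field, radial, circular, sections)
        np.testing.assert_allclose(prof.dor, 0.0, atol=1e-12)

    def test_45_degree_field_is_one_exactly(self, disk_cell):
        radial, circular, sections = _dor_inputs(disk_cell)
        field = _synthetic_field(disk_cell, np.pi / 4)
        prof = degree_of_radiality(field, radial, circular, sections)
        np.testing.assert_allclose(prof.dor, 1.0, atol=1e-9)

    def test_uniform_random_field_near_one(self):
        """DoR of uniformly random axial orientations tends to 1
        (E|cos| = E|sin| under a uniform angle), checked against a
        Monte-Carlo oracle on >= 1e5 pixels."""
        cell = mask_to_cell(make_rough_mask((185.0, 185.0)))
        radial, circular, sections = _dor_inputs(cell, K=2)
        rng = np.random.default_rng(0)
        angle = rng.uniform(0, np.pi, size=cell.shape)
        field = OrientationField(angle=angle, coherence=np.ones(cell.shape),
                                 valid=cell.hull.copy())
        prof = degree_of_radiality(field, radial, circular, sections)
        n = int(prof.n_pixels.sum())
        assert n >= 100_000
        pooled = prof.pooled_dor()
        assert abs(pooled - 1.0) < 0.02
        # independent Monte-Carlo oracle at the same sample size
        theta = rng.uniform(0, np.pi, size=n)
        oracle = np.abs(np.cos(theta)).sum() / np.abs(np.sin(theta)).sum()
        assert abs(pooled - oracle) < 0.02

    def test_empty_section_flagged(self, disk_cell):
        radial, circular, sections = _dor_inputs(disk_cell)
        field = _synthetic_field(disk_cell, 0.3)
        # invalidate everything in section 1
        field.valid[sections.section_index == 1] = False
        prof = degree_of_radiality(field, radial, circular, sections)
        assert prof.n_pixels[0] == 0 and np.isnan(prof.dor[0])
        assert np.isfinite(prof.dor[1:]).all()

    def test_shape_mismatch_rejected(self, disk_cell):
        radial, circular, sections = _dor_inputs(disk_cell)
        small = np.zeros((10, 10))
        field = OrientationField(angle=small, coherence=small, valid=small.astype(bool))
        with pytest.raises(ValueError, match="raster"):
            degree_of_radiality(field, radial, circular, sections)


class TestDorAt:
    def _profile(self, disk_cell):
        radial, circular, sections = _dor_inputs(disk_cell)
        return degree_of_radiality(_synthetic_field(disk_cell, 0.3),
                                   radial, circular, sections)

    def test_returns_requested_section(self, disk_cell):
        prof = self._profile(disk_cell)
        assert dor_at(prof, 2.0) == prof.dor[1]

    @pytest.mark.parametrize("bad", [0.0, 5.0])
    def test_out_of_range_distance_rejected(self, disk_cell, bad):
        with pytest.raises(KeyError):
            dor_at(self._profile(disk_cell), bad)


class TestPipelineProperties:
    def test_alpha_ordering_per_section(self):
        """Noise-free cells: DoR(alpha=1) > DoR(0.5) > 1 > DoR(0) in
        every section with enough clearly oriented pixels.

        The renders use cytoplasm == background (no intensity step at the
        footprint) with the ground-truth mask supplied, isolating the
        filament signal: the mask edge itself is a genuine tangential
        structure that otherwise dilutes the outermost section."""
        profs = {}
        for alpha in (0.0, 0.5, 1.0):
            spec = SyntheticCellSpec(radiality_alpha=alpha, noise_sigma=0.0,
                                     organizing_center_offset=(0.0, 0.0), seed=21,
                                     cytoplasm=5.0)
            img, truth = make_filament_cell(spec)
            profs[alpha] = dor_profile(img, cell=mask_to_cell(truth.mask),
                                       coherence_min=0.2)
        for k in range(4):
            enough = all(p.n_pixels[k] >= 50 for p in profs.values())
            if not enough:
                continue
            assert profs[1.0].dor[k] > profs[0.5].dor[k] > 1.0 > profs[0.0].dor[k]

    def test_rotation_equivariance(self):
        """Rotating the image by 90 degrees changes each section's DoR
        only through discretisation (< 3%)."""
        img, _ = make_filament_cell(SyntheticCellSpec(seed=8))
        prof = dor_profile(img)
        rot = ChannelImage(np.rot90(img.pixels).copy(), img.pixel_size_um)
        prof_rot = dor_profile(rot)
        rel = np.abs(prof_rot.dor - prof.dor) / prof.dor
        assert rel.max() < 0.03

    def test_intensity_scale_invariance(self):
        img, _ = make_filament_cell(SyntheticCellSpec(seed=8))
        prof = dor_profile(img)
        scaled = ChannelImage(img.pixels * 7.3, img.pixel_size_um)
        prof_s = dor_profile(scaled)
        np.testing.assert_allclose(prof_s.dor, prof.dor, rtol=1e-7)

    def test_profile_frame_layout(self):
        img, _ = make_filament_cell(SyntheticCellSpec(seed=8))
        df = dor_profile(img, cell_id="c7").to_frame()
        assert list(df.columns) == ["cell_id", "section", "relative_distance",
                                    "n_pixels", "dor"]
        assert (df["cell_id"] == "c7").all() and len(df) == 4
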