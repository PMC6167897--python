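import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from shapely.ops import unary_union

from tmeprox import (
    SimParams,
    fit_affine,
    generate_geometry,
    simulate_cells,
    simulate_cohort,
    simulate_serial_sections,
)
from tmeprox.synthetic import (
    NONRESPONDER_LIKE,
    RESPONDER_LIKE,
    render_marker_mask,
    simulate_specimen,
)
from dataclasses import replace


class TestGeometry:
    def test_zero_roughness_is_a_disk(self):
        params = SimParams(tumor_roughness=0.0, tumor_mean_radius_um=500.0)
        ann = generate_geometry(params)
        area = ann.tumor_polygons[0].area
        assert area == pytest.approx(np.pi * 500.0**2, rel=0.005)

    def test_same_seed_identical_vertices(self):
        a = generate_geometry(SimParams(seed=5))
        b = generate_geometry(SimParams(seed=5))
        assert a.tumor_polygons[0].equals_exact(b.tumor_polygons[0], 0.0)

    def test_polygons_simple_over_many_seeds(self):
        for seed in range(100):
            ann = generate_geometry(SimParams(seed=seed, tumor_roughness=0.2))
            poly = ann.tumor_polygons[0]
            assert poly.is_valid and poly.is_simple

    def test_necrosis_blob_generated_with_requested_area(self):
        ann = generate_geometry(SimParams(seed=1, necrosis_fraction=0.1))
        assert len(ann.exclusion_polygons) == 1
        frac = ann.exclusion_polygons[0].area / ann.tumor_polygons[0].area
        assert 0.03 < frac < 0.3


class TestSimulateCells:
    def test_zero_immune_intensity_yields_no_immune_cells(self):
        params = SimParams(seed=2, immune_peak_intensity=0.0)
        cells = simulate_cells(generate_geometry(params), params)
        assert cells.positive("NSE").all()

    def test_tumor_count_within_poisson_bounds(self):
        params = SimParams(seed=3, tumor_roughness=0.0, immune_peak_intensity=0.0)
        ann = generate_geometry(params)
        cells = simulate_cells(ann, params)
        area_mm2 = ann.tumor_polygons[0].area / 1e6
        expected = params.tumor_cell_intensity * area_mm2
        assert abs(len(cells) - expected) <= 3 * np.sqrt(expected)

    def test_same_seed_bit_identical(self):
        params = SimParams(seed=4)
        a = simulate_cells(generate_geometry(SimParams(seed=4)), params,
                           np.random.default_rng(9))
        b = simulate_cells(generate_geometry(SimParams(seed=4)), params,
                           np.random.default_rng(9))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_immune_cells_enriched_at_interface(self):
        params = SimParams(seed=5, tumor_roughness=0.0)
        ann = generate_geometry(params)
        cells = simulate_cells(ann, params)
        immune = cells.subset(~cells.positive("NSE"))
        import shapely

        d = shapely.distance(
            shapely.points(immune.xy), ann.tumor_polygons[0].boundary
        )
        near = (d < params.immune_decay_um).sum()
        far = ((d >= params.immune_decay_um) & (d < 2 * params.immune_decay_um)).sum()
        assert near > far  # exponential decay from the interface

    def test_adaptive_pdl1_correlates_with_local_pd1(self):
        params = SimParams(
            seed=6, pdl1_mode="adaptive", tumor_mean_radius_um=900.0,
            immune_peak_intensity=1500.0, adaptive_alpha=-2.0,
        )
        cells = simulate_cells(generate_geometry(params), params)
        assert len(cells) >= 5000
        rho = sps.spearmanr(
            _local_pd1_counts(cells, params.adaptive_radius_um),
            cells.positive("PDL1"),
        ).statistic
        assert rho > 0.1

    def test_constitutive_pdl1_independent_of_local_pd1(self):
        params = SimParams(
            seed=7, pdl1_mode="constitutive", tumor_mean_radius_um=900.0,
            immune_peak_intensity=1500.0, constitutive_p=0.3,
        )
        cells = simulate_cells(generate_geometry(params), params)
        tumor = cells.subset(cells.positive("NSE"))
        assert len(tumor) >= 5000
        rho = sps.spearmanr(
            _local_pd1_counts(tumor, params.adaptive_radius_um, within=cells),
            tumor.positive("PDL1"),
        ).statistic
        assert abs(rho) < 0.05

    def test_generated_specimens_pass_core_validation(self):
        from tmeprox.core_io import CellTable

        params = SimParams(seed=8, necrosis_fraction=0.08)
        cells = simulate_cells(generate_geometry(params), params)
        CellTable(cells.data, cells.markers)  # revalidates invariants

    def test_marker_mask_renders_positive_cells(self):
        params = SimParams(seed=9)
        ann = generate_geometry(params)
        cells = simulate_cells(ann, params)
        bounds = unary_union(ann.tumor_polygons).buffer(150).bounds
        mask = render_marker_mask(cells, "PDL1", bounds, pixel_size_um=4.0)
        assert mask.any() == cells.positive("PDL1").any()


def _local_pd1_counts(cells, radius, within=None):
    from scipy.spatial import cKDTree

    ref = cells if within is None else within
    pd1_xy = ref.xy[ref.positive("PD1")]
    if not len(pd1_xy):
        return np.zeros(len(cells))
    counts = cKDTree(pd1_xy).query_ball_point(cells.xy, radius, return_length=True)
    return counts.astype(float)


class TestSerialSections:
    def test_zero_jitter_zero_dropout_pure_rigid(self):
        params = SimParams(seed=10, section_jitter_um=0.0, section_dropout=0.0)
        cells = simulate_cells(generate_geometry(params), params)
        sections = simulate_serial_sections(cells, params)
        mapped = sections.true_transform.apply(sections.section_a.xy)
        assert np.max(np.abs(mapped - sections.section_b.xy)) < 1e-9

    def test_landmark_registration_recovers_inverse_transform(self):
        params = SimParams(seed=11, section_jitter_um=0.0, section_dropout=0.0)
        cells = simulate_cells(generate_geometry(params), params)
        s = simulate_serial_sections(cells, params)
        fit = fit_affine(
            s.landmarks[["moving_x", "moving_y"]].to_numpy(),
            s.landmarks[["fixed_x", "fixed_y"]].to_numpy(),
            model="rigid",
        )
        want = np.asarray(s.true_transform.inverse().matrix)
        assert np.max(np.abs(np.asarray(fit.transform.matrix) - want)) < 1e-6

    def test_dropout_rate_within_binomial_bounds(self):
        params = SimParams(seed=12, section_dropout=0.3)
        cells = simulate_cells(generate_geometry(params), params)
        s = simulate_serial_sections(cells, params)
        n = len(cells)
        expected = 0.7 * n
        assert abs(len(s.section_b) - expected) <= 3 * np.sqrt(n * 0.3 * 0.7)


class TestCohort:
    def test_fixed_seed_reproducible_table(self):
        a = simulate_cohort(3, 2, seed=42)
        b = simulate_cohort(3, 2, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_specimen_streams_insertion_order_independent(self):
        # specimen i is seeded by (seed, i): the responder arm's records do
        # not depend on how many non-responders follow
        a = simulate_cohort(3, 1, seed=13)
        b = simulate_cohort(3, 4, seed=13)
        pd.testing.assert_frame_equal(a.iloc[:3], b.iloc[:3])

    def test_responder_median_near_pd1_anchor(self):
        medians = [
            simulate_cohort(6, 1, seed=s)
            .query("responder")["pd1_density_total"]
            .median()
            for s in range(10)
        ]
        assert abs(np.median(medians) - 70.7) / 70.7 < 0.3

    def test_nonresponder_median_near_pd1_anchor(self):
        medians = [
            simulate_cohort(1, 6, seed=s)
            .query("~responder")["pd1_density_total"]
            .median()
            for s in range(10)
        ]
        assert abs(np.median(medians) - 6.7) / 6.7 < 0.3

    def test_adaptive_beats_constitutive_at_matched_marginals(self):
        # the discriminating property of the proximity biomarker: with the
        # same marginal PD-1/PD-L1 densities, spatially coupled (adaptive)
        # PD-L1 puts more PD-1+ cells within 20 um of a PD-L1+ cell
        matched = replace(
            NONRESPONDER_LIKE,
            pd1_density_median=70.7, cd8_density_median=264.0,
            pdl1_density_median=855.4,
        )
        adaptive = replace(matched, name="adaptive", pdl1_mode="adaptive")
        constitutive = replace(matched, name="constitutive", pdl1_mode="constitutive")
        a_prox, c_prox = [], []
        for seed in range(8):
            rng_a = np.random.default_rng([seed, 1])
            rng_c = np.random.default_rng([seed, 1])
            rec_a, *_ = simulate_specimen(adaptive, rng_a, "a")
            rec_c, *_ = simulate_specimen(constitutive, rng_c, "c")
            a_prox.append(rec_a["pd1_near_pdl1_density"])
            c_prox.append(rec_c["pd1_near_pdl1_density"])
        assert np.median(a_prox) > np.median(c_prox)

    def test_invalid_arm_sizes_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            simulate_cohort(0, 3, seed=0)
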