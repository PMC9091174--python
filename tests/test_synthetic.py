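"""Generators: planted ground truth, seeded determinism, geometric fidelity."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from ebmorph.synthetic import (CohortSpec, SectionSpec, StackSpec, gen_diameter_cohort,
                               gen_eb_mask, gen_marker_section, gen_nuclei_stack,
                               gen_qpcr_table)


class TestDiameterCohort:
    def test_zero_cv_measures_exact_stage_mean(self):
        spec = CohortSpec(stages=(("EB1", 250.0, 0.0),), n_per_stage=5, seed=1)
        table = gen_diameter_cohort(spec)
        assert np.allclose(table["diameter_um"], 250.0)

    def test_default_cohort_size_is_24(self):
        spec = CohortSpec(stages=(("EB1", 250.0, 0.03),), seed=0)
        table = gen_diameter_cohort(spec)
        assert table["eb_id"].nunique() == 24

    def test_direction_counts_between_2_and_8(self, two_stage_cohort):
        counts = two_stage_cohort.groupby("eb_id").size()
        assert counts.between(2, 8).all()

    def test_same_seed_is_bit_identical(self):
        spec = CohortSpec(stages=(("EB1", 250.0, 0.04),), n_per_stage=10, seed=7)
        pd.testing.assert_frame_equal(gen_diameter_cohort(spec),
                                      gen_diameter_cohort(spec))

    def test_carries_planted_true_diameters(self, two_stage_cohort):
        per_eb = two_stage_cohort.groupby("eb_id")["true_diameter_um"].nunique()
        assert (per_eb == 1).all()

    @pytest.mark.parametrize("kwargs", [
        {"stages": (("EB1", -5.0, 0.03),)},
        {"stages": (("EB1", 250.0, -0.1),)},
        {"stages": (("EB1", 250.0, 0.03),), "n_per_stage": 0},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortSpec(seed=0, **kwargs)


class TestNucleiStack:
    def test_full_labeling_paints_both_channels(self):
        spec = StackSpec(eb_radius_um=60, n_nuclei=20, labeled_fraction=1.0,
                         pixel_size_um=1.0, n_planes=1, noise_sd=0.0, seed=2)
        stack, gt = gen_nuclei_stack(spec)
        assert gt.n_labeled() == gt.n_total() == 20
        # every nucleus pixel lit in the EdU channel too
        assert np.array_equal(stack.channel(0)[0] > 0, stack.channel(1)[0] > 0)

    def test_exact_rounded_labeled_count(self):
        spec = StackSpec(eb_radius_um=160, n_nuclei=200, labeled_fraction=0.75,
                         pixel_size_um=1.0, n_planes=1, seed=3)
        _, gt = gen_nuclei_stack(spec)
        assert gt.n_labeled(plane=0) == 150

    def test_surface_mode_shifts_labeled_cells_outward(self):
        """Empirical mean radial position, surface vs uniform, over 10 seeds."""
        def mean_radius(mode, seed):
            spec = StackSpec(eb_radius_um=80, n_nuclei=40, labeled_fraction=0.5,
                             spatial_mode=mode, pixel_size_um=1.0, n_planes=1,
                             seed=seed)
            stack, gt = gen_nuclei_stack(spec)
            c = stack.data.shape[-1] / 2.0
            t = gt.table[gt.table["labeled"]]
            return np.hypot(t["x_px"] - c, t["y_px"] - c).mean()

        surf = np.mean([mean_radius("surface", s) for s in range(10)])
        unif = np.mean([mean_radius("uniform", s) for s in range(10)])
        assert surf > unif

    def test_ground_truth_matches_rendered_object_count(self, small_stack):
        stack, gt = small_stack
        for p in range(stack.n_planes):
            binary = stack.channel(0)[p] > 0.4
            assert ndi.label(binary)[1] == gt.n_total(plane=p)

    def test_seeded_determinism(self):
        spec = StackSpec(eb_radius_um=60, n_nuclei=20, n_planes=2, seed=9)
        s1, g1 = gen_nuclei_stack(spec)
        s2, g2 = gen_nuclei_stack(spec)
        assert np.array_equal(s1.data, s2.data)
        pd.testing.assert_frame_equal(g1.table, g2.table)

    def test_bad_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            StackSpec(pixel_size_um=0.0)


class TestMarkerSection:
    def test_zero_cavity_gives_bright_oct4_core(self):
        spec = SectionSpec(total_diameter_um=300, cavity_diameter_um=0.0,
                           exen_thickness_um=30, boundary_jitter_px=0, noise_sd=0,
                           seed=0)
        sec = gen_marker_section(spec)
        c = sec.data.shape[-1] // 2
        assert sec.channel("oct4")[c, c] == pytest.approx(spec.oct4_intensity)

    def test_zone_areas_match_analytic_annuli(self, archetype_section):
        """Rasterised zone areas vs πr² annuli within 2% at 500 px diameter."""
        sec = archetype_section
        gt = sec.ground_truth
        px_area = sec.pixel_size_um ** 2
        r_tot = gt["total_diameter_um"] / 2
        r_cav = gt["cavity_diameter_um"] / 2
        r_epi = r_tot - gt["exen_thickness_um"]
        gata4 = np.count_nonzero(sec.channel("gata4") > 0.5) * px_area
        oct4 = np.count_nonzero(sec.channel("oct4") > 0.5) * px_area
        assert gata4 == pytest.approx(np.pi * (r_tot**2 - r_epi**2), rel=0.02)
        assert oct4 == pytest.approx(np.pi * (r_epi**2 - r_cav**2), rel=0.02)

    def test_cavity_dark_in_both_channels(self, archetype_section):
        c = archetype_section.data.shape[-1] // 2
        assert archetype_section.channel("gata4")[c, c] < 0.1
        assert archetype_section.channel("oct4")[c, c] < 0.1

    def test_inconsistent_radii_rejected(self):
        with pytest.raises(ValueError):
            SectionSpec(total_diameter_um=100, cavity_diameter_um=80,
                        exen_thickness_um=20)

    def test_seeded_determinism(self):
        spec = SectionSpec(total_diameter_um=200, cavity_diameter_um=80,
                           exen_thickness_um=20, boundary_jitter_px=2, seed=4)
        assert np.array_equal(gen_marker_section(spec).data,
                              gen_marker_section(spec).data)


class TestEbMask:
    def test_deterministic_and_near_circular(self):
        m1 = gen_eb_mask(100, 0.02, seed=1)
        m2 = gen_eb_mask(100, 0.02, seed=1)
        assert np.array_equal(m1, m2)
        assert m1.sum() == pytest.approx(np.pi * 100**2, rel=0.05)


class TestQpcrTable:
    def test_no_effect_no_noise_gives_flat_ct(self):
        ct, truth = gen_qpcr_table(["Oct4"], ["A", "B"], noise_sd=0.0, seed=0)
        oct4 = ct[ct["gene"] == "Oct4"]
        assert oct4["ct"].nunique() == 1
        assert (truth["fold"] == 1.0).all()

    def test_planted_fold_4_lowers_ct_by_2_cycles(self):
        ct, _ = gen_qpcr_table(["Gata4"], ["ref", "treated"],
                               effects={"treated": {"Gata4": 4.0}},
                               noise_sd=0.0, seed=0)
        by_cond = ct[ct["gene"] == "Gata4"].groupby("sample")["ct"].mean()
        assert by_cond["ref"] - by_cond["treated"] == pytest.approx(2.0)

    def test_triplicates_by_default(self):
        ct, _ = gen_qpcr_table(["Oct4"], ["A"], seed=0)
        assert (ct.groupby(["sample", "gene"]).size() == 3).all()

    def test_reference_gene_always_present(self):
        ct, _ = gen_qpcr_table(["Oct4"], ["A", "B"], seed=0)
        assert set(ct[ct["gene"] == "Hprt"]["sample"]) == {"A", "B"}

    def test_reference_gene_among_targets_rejected(self):
        with pytest.raises(ValueError):
            gen_qpcr_table(["Hprt", "Oct4"], ["A"], seed=0)
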