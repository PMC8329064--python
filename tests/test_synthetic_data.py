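"""Generator contracts: geometry, determinism, and planted-truth recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import gbmregio as g
from gbmregio.segmentation import CLASS_MAP


class TestTissueSlide:
    def test_structure_free_slide_has_only_outer_bands(self):
        p = g.SlideLayoutParams(image_size=96, necrosis_blob_count=0,
                                mvp_blob_count=0, seed=2)
        sl = g.generate_tissue_slide(p)
        assert set(np.unique(sl.mask)) == {0, 1, 2, 3}  # BG, LE, IT, CT

    def test_seeded_determinism_is_byte_identical(self):
        p = g.SlideLayoutParams(image_size=96, seed=5)
        a, b = g.generate_tissue_slide(p), g.generate_tissue_slide(p)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    def test_labels_within_range_and_bg_is_disk_complement(self):
        p = g.SlideLayoutParams(image_size=128, seed=9)
        sl = g.generate_tissue_slide(p)
        assert sl.mask.max() <= 7
        s = p.image_size
        c = (s - 1) / 2.0
        yy, xx = np.ogrid[:s, :s]
        r = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
        outside = r > p.tissue_radius_fraction * s / 2.0
        assert np.array_equal(sl.mask == 0, outside)

    def test_necrosis_boundary_touches_pseudopalisading(self):
        p = g.SlideLayoutParams(image_size=160, necrosis_blob_count=2, seed=3)
        sl = g.generate_tissue_slide(p)
        ne = sl.mask == CLASS_MAP.index("CTne")
        pan = sl.mask == CLASS_MAP.index("CTpan")
        assert ne.any() and pan.any()
        # every CTne boundary pixel must have an 8-adjacent CTpan pixel
        from scipy import ndimage
        interior = ndimage.binary_erosion(ne)
        boundary = ne & ~interior
        pan_dilated = ndimage.binary_dilation(
            pan, structure=np.ones((3, 3), dtype=bool))
        assert (boundary <= pan_dilated).all()

    def test_invalid_band_fractions_rejected(self):
        p = g.SlideLayoutParams(band_fractions={"LE": 0.5, "IT": 0.4, "CT": 0.3})
        with pytest.raises(g.InvalidLayoutError):
            g.generate_tissue_slide(p)

    def test_nuclei_density_ratio_recovered(self):
        # CT at 40/1000px^2 vs LE at 5/1000px^2 -> ratio ~8, within [4, 16]
        ct_rate, le_rate = [], []
        for seed in range(10):
            p = g.SlideLayoutParams(image_size=128, necrosis_blob_count=0,
                                    mvp_blob_count=0, seed=seed,
                                    nuclei_density={"CT": 40.0, "LE": 5.0,
                                                    "IT": 15.0})
            sl = g.generate_tissue_slide(p)
            ct_area = (sl.mask == CLASS_MAP.index("CT")).sum()
            le_area = (sl.mask == CLASS_MAP.index("LE")).sum()
            ct_rate.append(len(sl.nuclei["CT"]) / ct_area)
            le_rate.append(len(sl.nuclei["LE"]) / le_area)
        ratio = np.mean(ct_rate) / np.mean(le_rate)
        assert 4 <= ratio <= 16


class TestCohort:
    def test_null_model_gives_constant_survival(self):
        plan = g.CohortPlan(n_patients=5, seed=1, image_size=64,
                            survival_noise_sd=1e-12,
                            survival_coefficients={})
        _, clinical, _, _ = g.generate_cohort(plan)
        expected = np.exp(plan.baseline_log_survival)
        assert np.allclose(clinical["survival_days"], expected, rtol=1e-6)

    def test_all_dead_and_positive_survival(self, cohort100):
        clin = cohort100["clinical"]
        assert (clin["vital_status"] == "dead").all()
        assert (clin["survival_days"] > 0).all()

    def test_degenerate_mutation_frequency(self):
        plan = g.CohortPlan(n_patients=8, seed=2, image_size=64,
                            mutation_frequencies={"TP53": 1.0})
        _, clinical, _, _ = g.generate_cohort(plan)
        assert clinical["mutations"].str.contains("TP53").all()

    def test_true_areas_sum_to_tissue_total(self, cohort100):
        areas = cohort100["areas"]
        slides = cohort100["slides"]
        for pid in list(areas.index)[:5]:
            tissue = np.mean([(sl.mask > 0).sum() for sl in slides[pid]])
            assert areas.loc[pid].sum() == pytest.approx(tissue)

    def test_measured_fractions_match_planted_dirichlet(self, cohort100):
        norm = g.normalize_areas(cohort100["areas"])
        diff = (norm - cohort100["truth"]["fractions"]).abs()
        assert diff.to_numpy().max() < 0.02

    def test_ols_on_true_areas_recovers_planted_coefficients(self):
        # generator self-check: the survival model is what it claims to be
        plan = g.CohortPlan(
            n_patients=500, seed=7, image_size=96, slides_per_patient=(1, 1),
            survival_coefficients={("ALL", "CT"): 0.6, ("ALL", "IT"): -0.8,
                                   ("PIK3R1", "IT"): -2.0})
        _, clinical, areas, truth = g.generate_cohort(plan)
        norm = g.normalize_areas(areas)
        z = (norm - norm.mean()) / norm.std(ddof=0)
        X = sm.add_constant(pd.DataFrame({
            "CT": z["CT"], "IT": z["IT"],
            "PIK3R1_IT": z["IT"] * truth["mutations"]["PIK3R1"].to_numpy()}))
        y = np.log(clinical.set_index("patient_id").loc[areas.index,
                                                        "survival_days"])
        fit = sm.OLS(y, X).fit()
        for name, true in [("CT", 0.6), ("IT", -0.8), ("PIK3R1_IT", -2.0)]:
            assert abs(fit.params[name] - true) < 2 * fit.bse[name]

    def test_planted_mutation_effect_detectable_across_seeds(self):
        # Pearson(survival, IT area) < 0 among PIK3R1 carriers, n=200
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            plan = g.CohortPlan(
                n_patients=200, seed=40 + seed, image_size=64,
                slides_per_patient=(1, 1),
                survival_coefficients={("PIK3R1", "IT"): -2.0})
            _, clinical, areas, truth = g.generate_cohort(plan)
            carriers = truth["mutations"].index[truth["mutations"]["PIK3R1"]]
            norm = g.normalize_areas(areas)
            surv = clinical.set_index("patient_id").loc[carriers,
                                                        "survival_days"]
            r = g.pearson(norm.loc[carriers, "IT"], surv)
            hits += r.rho < 0
        assert hits >= int(0.95 * n_seeds)


class TestExpression:
    def test_null_effect_gives_zero_mean_correlation(self, cohort100):
        plan = g.ExpressionPlan(n_genes=500, markers_per_region=50,
                                effect_size=0.0, detection_dropout=0.0,
                                seed=21)
        expr, truth = g.generate_expression(cohort100["areas"], plan)
        fr = g.normalize_areas(cohort100["areas"])
        rho, _ = g.gene_region_correlations(expr, fr)
        marker_rho = [rho.loc[gene, region] for gene, region in truth.items()]
        assert abs(np.mean(marker_rho)) < 0.05

    def test_no_dropout_means_no_zeros(self, cohort100):
        plan = g.ExpressionPlan(n_genes=400, markers_per_region=50,
                                detection_dropout=0.0, seed=22)
        expr, _ = g.generate_expression(cohort100["areas"], plan)
        assert (expr.to_numpy() > 0).all()

    def test_planted_markers_have_strong_rank_correlation(self, cohort100,
                                                          expr100):
        fr = g.normalize_areas(cohort100["areas"])
        rho, _ = g.gene_region_correlations(expr100["expr"], fr)
        marker_rho = [rho.loc[gene, region]
                      for gene, region in expr100["marker_truth"].items()]
        assert np.median(marker_rho) > 0.3

    def test_expression_deterministic(self, cohort100):
        plan = g.ExpressionPlan(n_genes=400, markers_per_region=50, seed=23)
        a, _ = g.generate_expression(cohort100["areas"], plan)
        b, _ = g.generate_expression(cohort100["areas"], plan)
        pd.testing.assert_frame_equal(a, b)


class TestCellTypeReferenceAndClusters:
    @pytest.mark.parametrize("entries_per_type", [1, 3])
    def test_occurrence_counts_match_construction(self, entries_per_type):
        ref = g.generate_celltype_reference(4, entries_per_type, 15, seed=3)
        by_type = {}
        for e in ref:
            by_type[e.cell_type_name] = by_type.get(e.cell_type_name, 0) + 1
        assert set(by_type.values()) == {entries_per_type}

    def test_disjoint_universes_have_no_cross_type_overlap(self):
        ref = g.generate_celltype_reference(3, 2, 15, seed=4)
        by_type = {}
        for e in ref:
            by_type.setdefault(e.cell_type_name, set()).update(e.ranked_genes)
        names = list(by_type)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                assert not (by_type[names[i]] & by_type[names[j]])

    def test_entries_of_one_type_share_most_genes(self):
        ref = g.generate_celltype_reference(2, 3, 20, seed=5)
        mine = [e for e in ref if e.cell_type_name == ref[0].cell_type_name]
        base = set(mine[0].ranked_genes)
        for e in mine[1:]:
            assert len(base & set(e.ranked_genes)) >= 0.5 * len(base)

    def test_planted_pair_above_matrix_mean_in_carriers(self):
        plan = g.LRPlan()
        mats, truth = g.generate_cluster_expression(plan, 3, seed=6)
        planted = truth[0]
        for pid in planted["patients"]:
            ce = mats[pid]
            mean = ce.values.to_numpy().mean()
            src = ce.clusters_of_type(planted["source_type"])[0]
            rcv = ce.clusters_of_type(planted["receiver_type"])[0]
            assert ce.values.loc[planted["ligand"], src] > mean
            assert ce.values.loc[planted["receptor"], rcv] > mean

    def test_decoy_receptor_absent_in_third_patient(self):
        plan = g.LRPlan()
        mats, truth = g.generate_cluster_expression(plan, 3, seed=6)
        decoy = truth[1]
        absent = [p for p in mats if p not in decoy["patients"]]
        for pid in absent:
            ce = mats[pid]
            rcv = ce.clusters_of_type(decoy["receiver_type"])[0]
            assert ce.values.loc[decoy["receptor"], rcv] == 0.0

    def test_cluster_matrices_deterministic(self):
        plan = g.LRPlan()
        a, _ = g.generate_cluster_expression(plan, 3, seed=8)
        b, _ = g.generate_cluster_expression(plan, 3, seed=8)
        for pid in a:
            pd.testing.assert_frame_equal(a[pid].values, b[pid].values)
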