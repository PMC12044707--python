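import numpy as np
import pandas as pd
import pytest

import immunosort as iso
from immunosort.validation import ValidationError

from conftest import make_composition


def tiny_dataset(matrix, patients, cell_types=None, umis=None, unit="TPM"):
    matrix = np.asarray(matrix, dtype=float)
    cells = [f"c{i}" for i in range(matrix.shape[0])]
    obs = pd.DataFrame({"patient": patients}, index=cells)
    if cell_types is not None:
        obs["cell_type"] = cell_types
    if umis is not None:
        obs["umi_total"] = umis
    genes = [f"G{i}" for i in range(matrix.shape[1])]
    return iso.SingleCellDataset(
        matrix=pd.DataFrame(np.asarray(matrix, dtype=float), index=cells, columns=genes),
        obs=obs,
        unit=unit,
    )


class TestQCFilter:
    def test_min_genes_rule_removes_sparse_cell(self):
        m = np.zeros((2, 300))
        m[0, :150] = 1.0  # 150 expressed genes
        m[1, :250] = 1.0
        d = tiny_dataset(m, ["p1", "p1"])
        kept, report = iso.qc_filter(d, iso.QCConfig(min_genes=200))
        assert kept.n_cells == 1
        assert report.n_removed_by_rule["min_genes"] == 1

    def test_mito_fraction_rule(self):
        genes = ["MT-A", "MT-B", "G1", "G2"]
        m = pd.DataFrame(
            [[35.0, 0.0, 65.0, 0.0], [10.0, 0.0, 80.0, 10.0]],
            index=["c0", "c1"], columns=genes,
        )
        obs = pd.DataFrame({"patient": ["p", "p"]}, index=["c0", "c1"])
        d = iso.SingleCellDataset(matrix=m, obs=obs)
        kept, report = iso.qc_filter(d, iso.QCConfig(max_mito_frac=0.30))
        assert kept.cell_ids == ["c1"]
        assert report.n_removed_by_rule["max_mito"] == 1

    def test_cell_counted_under_every_violated_rule(self):
        m = np.zeros((2, 100))
        m[0, :5] = 1.0
        m[1, :50] = 1.0
        d = tiny_dataset(m, ["p", "p"], umis=[50000, 100])
        cfg = iso.QCConfig(min_genes=10, max_umis=30000)
        kept, report = iso.qc_filter(d, cfg)
        assert report.n_removed_by_rule == {"min_genes": 1, "max_umis": 1}
        assert report.n_cells_kept == 1

    def test_planted_violations_match_brute_force(self):
        """QC oracle: kept set equals independent rule-by-rule re-application."""
        cfg = iso.SimulationConfig(
            n_celltypes=6, n_genes=300, markers_per_type=8,
            n_patients=4, cells_per_patient=250, seed=71,
        )
        cells = iso.simulate_cells(cfg)
        qc = iso.QCConfig(min_genes=50, max_genes=250, max_umis=30000, max_mito_frac=0.30)
        planted_d, planted = iso.inject_qc_failures(
            cells, qc, {"low_genes": 0.02, "high_genes": 0.02,
                        "high_umi": 0.02, "high_mito": 0.02}, seed=72,
        )
        kept, report = iso.qc_filter(planted_d, qc)

        # brute-force oracle, reimplemented from the rule statements
        X = planted_d.matrix.to_numpy()
        genes = planted_d.gene_ids
        mito = np.array([g.startswith("MT-") for g in genes])
        expressed = (X > 0).sum(axis=1)
        umi = planted_d.obs["umi_total"].to_numpy(dtype=float)
        frac = X[:, mito].sum(axis=1) / X.sum(axis=1)
        ok = (expressed >= 50) & (expressed <= 250) & (umi <= 30000) & (frac <= 0.30)
        expected_kept = [c for c, keep in zip(planted_d.cell_ids, ok) if keep]
        assert kept.cell_ids == expected_kept
        rule_of = {"low_genes": "min_genes", "high_genes": "max_genes",
                   "high_umi": "max_umis", "high_mito": "max_mito"}
        for plant_rule, ids in planted.items():
            for cid in ids:
                assert cid not in kept.cell_ids
        for plant_rule, qc_rule in rule_of.items():
            assert report.n_removed_by_rule[qc_rule] >= len(planted[plant_rule])

    def test_idempotent(self):
        cfg = iso.SimulationConfig(n_celltypes=4, n_genes=150, markers_per_type=6,
                                   n_patients=2, cells_per_patient=100, seed=73,
                                   dropout_rate=0.5)
        cells = iso.simulate_cells(cfg)
        qc = iso.QCConfig(min_genes=40, max_mito_frac=0.5)
        once, _ = iso.qc_filter(cells, qc)
        twice, report = iso.qc_filter(once, qc)
        assert twice.cell_ids == once.cell_ids
        assert all(v == 0 for v in report.n_removed_by_rule.values())

    def test_all_cells_removed_is_error(self):
        m = np.ones((2, 10))
        d = tiny_dataset(m, ["p", "p"])
        with pytest.raises(ValidationError, match="every cell"):
            iso.qc_filter(d, iso.QCConfig(min_genes=100))

    def test_unknown_housekeeping_genes_warn(self):
        m = np.ones((2, 10)) * 5
        d = tiny_dataset(m, ["p", "p"])
        cfg = iso.QCConfig(housekeeping_genes=("G0", "NOPE"), min_housekeeping_expr=0.5)
        with pytest.warns(UserWarning, match="NOPE"):
            kept, _ = iso.qc_filter(d, cfg)
        assert kept.n_cells == 2


class TestGateTCells:
    def _t_dataset(self, cd4, cd8a, cd8b, label="T cell"):
        m = pd.DataFrame(
            [[cd4, cd8a, cd8b, 10.0]], index=["c0"],
            columns=["CD4", "CD8A", "CD8B", "ACTB"],
        )
        obs = pd.DataFrame({"patient": ["p"], "cell_type": [label]}, index=["c0"])
        return iso.SingleCellDataset(matrix=m, obs=obs)

    @pytest.mark.parametrize(
        "cd4,cd8a,cd8b,expected",
        [
            (5.0, 0.0, 0.0, "CD4_T"),       # CD4+ CD8A- CD8B-
            (0.0, 3.0, 2.0, "CD8_T"),       # CD8A+ CD8B+ CD4-
            (2.0, 2.0, 0.0, "unassigned"),  # double positive fails both gates
        ],
    )
    def test_gating_rules(self, cd4, cd8a, cd8b, expected):
        d = self._t_dataset(cd4, cd8a, cd8b)
        gated = iso.gate_t_cells(d, expr_threshold=0.0)
        assert gated.obs.loc["c0", "cell_type"] == expected

    def test_non_t_cells_untouched(self):
        d = self._t_dataset(5.0, 0.0, 0.0, label="B")
        m2 = d.matrix.copy()
        m2.loc["c1"] = [4.0, 0.0, 0.0, 1.0]
        obs2 = d.obs.copy()
        obs2.loc["c1"] = {"patient": "p", "cell_type": "T cell"}
        d2 = iso.SingleCellDataset(matrix=m2, obs=obs2)
        gated = iso.gate_t_cells(d2)
        assert gated.obs.loc["c0", "cell_type"] == "B"
        assert gated.obs.loc["c1", "cell_type"] == "CD4_T"

    def test_missing_gating_gene_rejected(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["c0"], columns=["CD4", "ACTB"])
        obs = pd.DataFrame({"patient": ["p"], "cell_type": ["T cell"]}, index=["c0"])
        d = iso.SingleCellDataset(matrix=m, obs=obs)
        with pytest.raises(ValidationError, match="CD8A"):
            iso.gate_t_cells(d)

    def test_threshold_in_data_units(self):
        d = self._t_dataset(1.5, 1.0, 0.5)
        gated = iso.gate_t_cells(d, expr_threshold=1.0)
        assert gated.obs.loc["c0", "cell_type"] == "CD4_T"


class TestGroundTruth:
    def test_counting_proportions(self):
        labels = ["B"] * 10 + ["CD4_T"] * 30 + ["CD8_T"] * 60
        m = np.ones((100, 5))
        d = tiny_dataset(m, ["p1"] * 100, cell_types=labels)
        truth, excluded = iso.ground_truth_composition(
            d, ["B", "CD4_T", "CD8_T"], min_immune_cells=10
        )
        np.testing.assert_allclose(truth.data.loc["p1"], [0.1, 0.3, 0.6])
        assert excluded == []

    def test_low_immune_fraction_patient_excluded(self):
        labels = ["B"] * 5 + ["Tumor"] * 95 + ["B"] * 50 + ["Tumor"] * 50
        patients = ["p_low"] * 100 + ["p_ok"] * 100
        d = tiny_dataset(np.ones((200, 4)), patients, cell_types=labels)
        truth, excluded = iso.ground_truth_composition(
            d, ["B"], min_immune_frac=0.20, min_immune_cells=1
        )
        assert excluded == ["p_low"]
        assert truth.sample_ids == ["p_ok"]

    def test_min_immune_cells_rule(self):
        labels = ["B"] * 30 + ["B"] * 80
        patients = ["p_few"] * 30 + ["p_many"] * 80
        d = tiny_dataset(np.ones((110, 3)), patients, cell_types=labels)
        truth, excluded = iso.ground_truth_composition(d, ["B"], min_immune_cells=50)
        assert excluded == ["p_few"]

    def test_counts_match_independent_oracle(self, rng):
        cfg = iso.SimulationConfig(n_celltypes=5, n_genes=150, markers_per_type=6,
                                   n_patients=3, cells_per_patient=200, seed=79,
                                   merge_t_labels=False)
        d = iso.simulate_cells(cfg)
        types = cfg.celltype_names
        truth, _ = iso.ground_truth_composition(d, types, min_immune_cells=1)
        for patient in truth.sample_ids:
            sub = d.obs[d.obs["patient"] == patient]
            counts = np.array([(sub["cell_type"] == t).sum() for t in types], float)
            np.testing.assert_allclose(truth.data.loc[patient], counts / counts.sum())

    def test_empty_panel_rejected(self):
        d = tiny_dataset(np.ones((2, 3)), ["p", "p"], cell_types=["B", "B"])
        with pytest.raises(ValidationError, match="non-empty"):
            iso.ground_truth_composition(d, [])


class TestMakePseudobulk:
    def test_elementwise_mean(self):
        d = tiny_dataset([[2, 0, 4], [0, 2, 0]], ["p1", "p1"])
        pb = iso.make_pseudobulk(d)
        np.testing.assert_allclose(pb.data["p1"], [1.0, 1.0, 2.0])

    def test_single_cell_patient_identity(self):
        d = tiny_dataset([[2, 0, 4], [1, 1, 1]], ["p1", "p2"])
        pb = iso.make_pseudobulk(d)
        np.testing.assert_allclose(pb.data["p1"], [2, 0, 4])
        np.testing.assert_allclose(pb.data["p2"], [1, 1, 1])

    def test_matches_numpy_mean_and_permutation_commutes(self, rng):
        m = rng.uniform(0, 100, size=(100, 20))
        d = tiny_dataset(m, ["p"] * 100)
        pb = iso.make_pseudobulk(d)
        np.testing.assert_allclose(pb.data["p"], m.mean(axis=0), atol=1e-12)
        perm = rng.permutation(100)
        d2 = d.subset_cells([d.cell_ids[i] for i in perm])
        pb2 = iso.make_pseudobulk(d2)
        np.testing.assert_allclose(pb2.data["p"], pb.data["p"], atol=1e-12)


class TestRescaleShared:
    def test_renormalization_over_shared_types(self):
        pred = make_composition(
            [[0.1, 0.2, 0.1, 0.1, 0.5]],
            types=["a", "b", "c", "d", "extra"],
        )
        truth = make_composition([[0.25, 0.25, 0.25, 0.25]], types=["a", "b", "c", "d"])
        t2, p2 = iso.rescale_shared(truth, pred)
        np.testing.assert_allclose(p2.values[0], [0.2, 0.4, 0.2, 0.2])
        np.testing.assert_allclose(t2.values[0], [0.25] * 4)

    def test_already_restricted_truth_unchanged(self):
        truth = make_composition([[0.3, 0.7]], types=["a", "b"])
        pred = make_composition([[0.2, 0.3, 0.5]], types=["a", "b", "c"])
        t2, _ = iso.rescale_shared(truth, pred)
        np.testing.assert_allclose(t2.values, truth.values)

    def test_rows_on_simplex_property(self, rng):
        truth = make_composition(rng.dirichlet(np.ones(4), 6), types=list("abcd"))
        pred = make_composition(rng.dirichlet(np.ones(6), 6), types=list("abcdef"))
        t2, p2 = iso.rescale_shared(truth, pred)
        np.testing.assert_allclose(t2.values.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(p2.values.sum(axis=1), 1.0, atol=1e-9)

    def test_disjoint_panels_rejected(self):
        truth = make_composition([[1.0]], types=["x"])
        pred = make_composition([[1.0]], types=["y"])
        with pytest.raises(ValidationError, match="share no"):
            iso.rescale_shared(truth, pred)

    def test_sample_mismatch_rejected(self):
        truth = make_composition([[1.0, 0.0]], samples=["s1"], types=["a", "b"])
        pred = make_composition([[1.0, 0.0]], samples=["s2"], types=["a", "b"])
        with pytest.raises(ValidationError, match="mismatch"):
            iso.rescale_shared(truth, pred)


class TestEvaluate:
    def test_perfect_prediction(self, rng):
        w = rng.dirichlet(np.ones(4), 6)
        truth = make_composition(w)
        pred = make_composition(w.copy())
        rep = iso.evaluate(truth, pred)
        assert rep.pooled_r == pytest.approx(1.0)
        assert rep.pooled_rmse == pytest.approx(0.0, abs=1e-15)

    def test_anticorrelated_two_type_panel(self):
        t = np.array([[0.1, 0.9], [0.4, 0.6], [0.7, 0.3]])
        truth = make_composition(t)
        pred = make_composition(1 - t)
        rep = iso.evaluate(truth, pred)
        for ct in rep.per_celltype.index:
            assert rep.per_celltype.loc[ct, "pearson_r"] == pytest.approx(-1.0)

    def test_constant_vector_reported_undefined(self):
        truth = make_composition([[0.5, 0.5], [0.5, 0.5]])
        pred = make_composition([[0.4, 0.6], [0.6, 0.4]])
        rep = iso.evaluate(truth, pred)
        assert not rep.per_celltype["r_defined"].any()
        assert np.isnan(rep.per_celltype["pearson_r"]).all()

    def test_rmse_recovers_noise_scale(self):
        """RMSE against truth+N(0, sigma) concentrates near sigma (MC check)."""
        rng = np.random.default_rng(83)
        sigma = 0.03
        t = rng.dirichlet(np.ones(5), 200)
        noise = rng.normal(0, sigma, size=t.shape)
        p = t + noise
        diffs = (p - t).ravel()
        rmse = float(np.sqrt(np.mean(diffs**2)))
        assert rmse == pytest.approx(sigma, rel=0.1)
        # and evaluate() computes exactly this pooled RMSE on clipped tables
        p2 = np.clip(p, 1e-9, None)
        p2 = p2 / p2.sum(axis=1, keepdims=True)
        rep = iso.evaluate(make_composition(t), make_composition(p2))
        expected = np.sqrt(np.mean((p2 - t) ** 2))
        assert rep.pooled_rmse == pytest.approx(expected, abs=1e-12)


class TestRunValidation:
    def test_end_to_end_recovery_noise_free(self, tmp_path):
        cfg = iso.SimulationConfig(
            n_celltypes=8, n_genes=300, markers_per_type=8,
            n_patients=6, cells_per_patient=300,
            lognormal_sigma=0.0, dropout_rate=0.0, seed=89,
        )
        cells = iso.simulate_cells(cfg)
        sig = iso.true_signature(cfg)
        res = iso.run_validation(
            cells, iso.QCConfig(min_genes=10), sig,
            immune_types=cfg.celltype_names, min_immune_cells=5,
            out_dir=tmp_path / "run",
        )
        assert res.report.pooled_r > 0.99
        for name in ("truth_rescaled.csv", "prediction_rescaled.csv",
                     "pseudobulk.csv", "evaluation.csv", "qc_report.csv"):
            assert (tmp_path / "run" / name).exists()

    def test_single_patient_cohort_rejected(self):
        cfg = iso.SimulationConfig(n_celltypes=4, n_genes=150, markers_per_type=6,
                                   n_patients=1, cells_per_patient=100, seed=91,
                                   merge_t_labels=False)
        cells = iso.simulate_cells(cfg)
        sig = iso.true_signature(cfg)
        with pytest.raises(ValidationError, match="undefined"):
            iso.run_validation(cells, iso.QCConfig(), sig,
                               immune_types=cfg.celltype_names, min_immune_cells=1,
                               gate_t_subsets=False)


class TestPresets:
    def test_dataset_profiles_follow_protocol(self):
        nsclc = iso.PRESETS["nsclc"]
        assert nsclc.qc.min_genes == 200
        assert nsclc.qc.max_genes == 5000
        assert nsclc.qc.max_umis == 30000
        assert nsclc.qc.max_mito_frac == pytest.approx(0.30)
        assert nsclc.min_immune_frac == pytest.approx(0.20)
        assert set(nsclc.immune_types) == {"T cell", "B", "Mast", "Neutrophil"}
        assert iso.PRESETS["melanoma"].qc.min_genes == 1700
        assert iso.PRESETS["hnscc"].qc.min_genes == 2000

    def test_preset_file_parsing(self, tmp_path):
        from immunosort.validation import read_preset_file

        p = tmp_path / "custom.cfg"
        p.write_text("min_genes = 500  # comment\nmax_mito_frac=0.2\n\n")
        assert read_preset_file(p) == {"min_genes": "500", "max_mito_frac": "0.2"}
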