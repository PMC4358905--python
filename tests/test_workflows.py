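import numpy as np
import pytest

from qsarlab import chem_io, descriptors, store
from qsarlab.synth import gen_toy_sdf
from qsarlab.workflows import (
    BuildConfig,
    build_workflow,
    predict_workflow,
    register_stage,
    resolve_stage,
    retrain,
    unregister_stage,
)

from conftest import record_from_smiles


class TestBuildConfig:
    def test_round_trip(self):
        cfg = BuildConfig(activity_field="pKi", scaling="center", A_max=4,
                          ffd_enabled=True, embedded_fields=["logP"],
                          label_map={"pos": 1, "neg": 0}, seed=7)
        back = BuildConfig.from_text(cfg.to_text())
        assert back == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown key 'banana'"):
            BuildConfig.from_text("banana=1\n")

    def test_malformed_line(self):
        with pytest.raises(ValueError, match="key=value"):
            BuildConfig.from_text("just words\n")

    def test_comments_and_blanks_ok(self):
        cfg = BuildConfig.from_text("# comment\n\nscaling=center\n")
        assert cfg.scaling == "center"


class TestBuildWorkflow:
    def test_toy_build_quality(self, tmp_path, toy_sdf):
        path, _ = toy_sdf
        report = build_workflow(tmp_path / "m", "TOY", path)
        assert report.q2[report.A_opt - 1] >= 0.99
        assert report.version_path.exists()

    def test_deterministic(self, tmp_path, toy_sdf):
        path, _ = toy_sdf
        r1 = build_workflow(tmp_path / "m1", "TOY", path)
        r2 = build_workflow(tmp_path / "m2", "TOY", path)
        assert np.array_equal(r1.q2, r2.q2)
        assert np.array_equal(r1.recalculated, r2.recalculated)
        assert r1.var_names == r2.var_names

    def test_too_small(self, tmp_path):
        sdf = tmp_path / "tiny.sdf"
        gen_toy_sdf(3, seed=1, path=sdf)
        with pytest.raises(ValueError, match="too small"):
            build_workflow(tmp_path / "m", "TINY", sdf)

    def test_single_class_qualitative(self, tmp_path):
        sdf = tmp_path / "one.sdf"
        gen_toy_sdf(10, seed=1, path=sdf, rule=lambda v: 1.0)
        cfg = BuildConfig(activity_type="qualitative",
                          label_map={"1.0": 1, "0.0": 0})
        with pytest.raises(ValueError, match="single class"):
            build_workflow(tmp_path / "m", "ONE", sdf, cfg)

    def test_quality_table_lists_every_dimensionality(self, tmp_path, toy_sdf):
        path, _ = toy_sdf
        report = build_workflow(tmp_path / "m", "TOY", path)
        table = report.quality_table()
        assert len(table.splitlines()) == report.A_max + 1


class TestPredictWorkflow:
    def test_training_copy_detection(self, tmp_path, toy_sdf):
        path, _ = toy_sdf
        root = tmp_path / "m"
        build_workflow(root, "TOY", path)
        results = predict_workflow(root, "TOY", 0, path)
        series = chem_io.read_sdf(path)
        for res, rec in zip(results, series.records):
            assert res.is_training_copy is True
            assert res.y_pred == float(rec.extra_fields["activity"])

    def test_recalculated_consistency(self, tmp_path, toy_sdf):
        path, _ = toy_sdf
        root = tmp_path / "m"
        report = build_workflow(root, "TOY", path)
        results = predict_workflow(root, "TOY", 0, path)
        scores = np.array([r.score for r in results])
        assert np.max(np.abs(scores - report.recalculated)) < 1e-10

    def test_descriptor_rows_bit_identical(self, tmp_path, toy_sdf):
        path, _ = toy_sdf
        root = tmp_path / "m"
        build_workflow(root, "TOY", path)
        _, bundle = store.load_version(root, "TOY", 0)
        series = chem_io.read_sdf(path)
        series.records = [chem_io.normalize(r) for r in series.records]
        matrix, _ = descriptors.extract(series)
        X_pred = descriptors.align_to_model(matrix, bundle.var_names,
                                            bundle.descriptor_set_id)
        # the stored scaled training matrix was produced from the build-time
        # descriptor rows; the predict-time rows must scale to the same bits
        assert np.array_equal(bundle.pls.scaling.apply(X_pred),
                              bundle.adan_state.training_Xs)

    def test_unknown_version(self, tmp_path, toy_sdf):
        path, _ = toy_sdf
        root = tmp_path / "m"
        build_workflow(root, "TOY", path)
        with pytest.raises(FileNotFoundError):
            predict_workflow(root, "TOY", 99, path)

    def test_outlier_gets_nonzero_category(self, tmp_path, toy_sdf):
        path, _ = toy_sdf
        root = tmp_path / "m"
        build_workflow(root, "TOY", path)
        # training molecules have no phosphorus or rings; build a big
        # decorated query far outside the training space
        query = tmp_path / "query.sdf"
        rec = record_from_smiles("OP(=O)(O)OP(=O)(O)OP(=O)(O)OCC1OC(C(O)C1O)n1cnc2c(N)ncnc21", "atp")
        chem_io.write_sdf([rec], query)
        res = predict_workflow(root, "TOY", 0, query)[0]
        assert np.isfinite(res.y_pred)
        assert res.adan_category >= 1


class TestRetrain:
    def test_concatenation_with_dedup(self, tmp_path, toy_sdf):
        path, _ = toy_sdf
        root = tmp_path / "m"
        build_workflow(root, "TOY", path)
        store.publish(root, "TOY")
        # new batch: 10 fresh molecules, 2 of which duplicate training ones
        new_sdf = tmp_path / "new.sdf"
        gen_toy_sdf(10, seed=777, path=new_sdf)
        orig = chem_io.read_sdf(path)
        new = chem_io.read_sdf(new_sdf)
        dup_records = orig.records[:2]
        chem_io.write_sdf(new.records + dup_records, new_sdf)
        n_unique_new = len({
            chem_io.normalize(r).structure_key for r in new.records
        } - {chem_io.normalize(r).structure_key for r in orig.records})
        report = retrain(root, "TOY", new_sdf)
        assert report.n == 30 + n_unique_new

    def test_version_advances_after_retrain(self, tmp_path, toy_sdf):
        path, _ = toy_sdf
        root = tmp_path / "m"
        build_workflow(root, "TOY", path)
        assert store.publish(root, "TOY") == 1
        new_sdf = tmp_path / "new.sdf"
        gen_toy_sdf(8, seed=55, path=new_sdf)
        retrain(root, "TOY", new_sdf)
        assert store.publish(root, "TOY") == 2

    def test_confidential_only_tag(self, tmp_path, toy_sdf):
        path, _ = toy_sdf
        root = tmp_path / "m"
        build_workflow(root, "TOY", path)
        conf = tmp_path / "conf.txt"
        store.export_confidential(root, "TOY", 0, conf)
        store.import_confidential(root, "SECRET", conf)
        with pytest.raises(ValueError, match="confidential"):
            retrain(root, "SECRET", path)


class TestStageOverrides:
    def test_fallback_to_builtin(self):
        assert resolve_stage("anytag", "extract").__name__ == "_builtin_extract"

    def test_unknown_stage(self):
        with pytest.raises(ValueError, match="unknown stage"):
            register_stage("t", "foo", lambda: None)
        with pytest.raises(ValueError, match="unknown stage"):
            resolve_stage("t", "foo")

    def test_decision_tree_predict_override(self, tmp_path, toy_sdf):
        path, truth = toy_sdf
        root = tmp_path / "m"

        def tree_predict(bundle, X):
            # two-rule tree on carbon count and Wiener index
            i_c = bundle.var_names.index("n_C")
            i_w = bundle.var_names.index("wiener")
            return np.where(X[:, i_c] >= 5,
                            np.where(X[:, i_w] >= 50, 3.0, 2.0), 1.0)

        register_stage("TREE", "predict", tree_predict)
        build_workflow(root, "TREE", path,
                       BuildConfig(detect_training_copy=False))
        meta, bundle = store.load_version(root, "TREE", 0)
        assert meta.custom is True
        results = predict_workflow(root, "TREE", 0, path)
        assert set(r.y_pred for r in results) <= {1.0, 2.0, 3.0}

    def test_override_leaves_other_stages_unchanged(self, tmp_path, toy_sdf):
        path, _ = toy_sdf
        root = tmp_path / "m"
        plain = build_workflow(root, "PLAIN", path)

        register_stage("OVR", "predict", lambda bundle, X: np.zeros(len(X)))
        overridden = build_workflow(root, "OVR", path)
        # normalize/extract/build unaffected by the predict override
        assert np.array_equal(plain.q2, overridden.q2)
        assert np.array_equal(plain.recalculated, overridden.recalculated)
        assert plain.var_names == overridden.var_names

        unregister_stage("OVR")
        results = predict_workflow(root, "OVR", 0, path)
        scores = np.array([r.score for r in results])
        plain_scores = np.array(
            [r.score for r in predict_workflow(root, "PLAIN", 0, path)])
        assert np.max(np.abs(scores - plain_scores)) < 1e-12
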