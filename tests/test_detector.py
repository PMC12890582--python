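"""Per-site models, max fusion, transfer training, patient-level cross-validation."""

import numpy as np
import pytest

from cardioscreen.cohort import PatientRecord, Recording, Sex, AgeBand, Setting, Site, EchoReport
from cardioscreen.detector import (
    MissingDataError,
    ModelConfig,
    SiteModel,
    VHDDetector,
    VHDDetectorResults,
    cross_validate,
    finetune_vhd,
    predict_patient,
    predict_recording,
    pretrain_murmur,
    _new_models,
)
from cardioscreen.preprocess import PreprocConfig, preprocess_recording


class _ConstScorer:
    """Stub emitting a fixed probability, for fusion-rule tests."""

    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(X.shape[1], self.value)


def _patient(pid="p0", sites=(Site.A, Site.T, Site.M), sig_grades=None):
    rng = np.random.default_rng(0)
    echo = EchoReport.from_grades(**(sig_grades or {}))
    recs = {s: [] for s in Site}
    for s in sites:
        recs[s] = [Recording(site=s, samples=rng.normal(0, 0.1, 4000), fs=4000.0)]
    return PatientRecord(id=pid, sex=Sex.FEMALE, age_band=AgeBand.FROM_65_TO_80,
                         setting=Setting.PRIMARY_CARE, echo=echo, recordings=recs)


def _const_models(values: dict[Site, float]):
    return {s: SiteModel(site=s, scorer=_ConstScorer(v)) for s, v in values.items()}


class TestFusion:
    def test_fused_is_max_over_used_sites(self):
        models = _const_models({Site.A: 0.2, Site.T: 0.9, Site.M: 0.4})
        pred = predict_patient(models, _patient(), {Site.A, Site.T, Site.M})
        assert pred.fused == 0.9
        assert pred.per_site[Site.T] == 0.9

    def test_singleton_site(self):
        models = _const_models({Site.M: 0.37})
        pred = predict_patient(models, _patient(), {Site.M})
        assert pred.fused == pred.per_site[Site.M] == 0.37

    def test_superset_never_lowers_fused_probability(self):
        models = _const_models({Site.A: 0.1, Site.T: 0.8, Site.M: 0.3})
        p = _patient()
        sub = predict_patient(models, p, {Site.A}).fused
        sup = predict_patient(models, p, {Site.A, Site.T}).fused
        full = predict_patient(models, p, {Site.A, Site.T, Site.M}).fused
        assert sub <= sup <= full

    def test_missing_data_error(self):
        models = _const_models({Site.P: 0.5})
        with pytest.raises(MissingDataError):
            predict_patient(models, _patient(sites=(Site.A,)), {Site.P})

    def test_site_mismatch_rejected(self):
        m = SiteModel(site=Site.A, scorer=_ConstScorer(0.5))
        spec = preprocess_recording(_patient().recordings[Site.M][0])
        with pytest.raises(ValueError, match="mismatch"):
            predict_recording(m, spec)

    def test_untrained_model_predicts_half(self):
        models = _new_models(ModelConfig(hidden_size=4), PreprocConfig())
        spec = preprocess_recording(_patient().recordings[Site.A][0])
        assert predict_recording(models[Site.A], spec) == 0.5


TINY = ModelConfig(hidden_size=6, max_epochs=2, batch_size=16, val_fraction=0.0, seed=9)


class TestTraining:
    def test_pretrain_sets_provenance_and_reduces_loss(self, tiny_cohort, tiny_features):
        models = _new_models(TINY, PreprocConfig(), sites=(Site.A,))
        pretrain_murmur(models, tiny_cohort, TINY, features=tiny_features)
        m = models[Site.A]
        assert m.training_provenance == "pretrained_murmur"
        hist = m.history["pretrain"]
        assert hist[-1]["train_loss"] <= hist[0]["train_loss"]

    def test_finetune_after_pretrain_changes_provenance(self, tiny_cohort, tiny_features):
        models = _new_models(TINY, PreprocConfig(), sites=(Site.M,))
        pretrain_murmur(models, tiny_cohort, TINY, features=tiny_features)
        finetune_vhd(models, tiny_cohort, TINY, features=tiny_features)
        assert models[Site.M].training_provenance == "finetuned_vhd"

    def test_empty_cohort_rejected(self):
        models = _new_models(TINY, PreprocConfig(), sites=(Site.A,))
        with pytest.raises(ValueError, match="empty"):
            pretrain_murmur(models, [], TINY)

    def test_seeded_training_is_bit_reproducible(self, tiny_cohort, tiny_features):
        weights = []
        for _ in range(2):
            models = _new_models(TINY, PreprocConfig(), sites=(Site.A,))
            finetune_vhd(models, tiny_cohort, TINY, features=tiny_features)
            weights.append(models[Site.A].scorer.get_weights())
        for k in weights[0]:
            np.testing.assert_array_equal(weights[0][k], weights[1][k])

    def test_fit_predict_roundtrip_and_save_load(self, tiny_cohort, tiny_features, tmp_path):
        det = VHDDetector(tiny_cohort, TINY, features=tiny_features)
        res = det.fit(pretrain=False)
        df = res.predict(tiny_cohort, features=tiny_features)
        assert set(df.columns) >= {"id", "label", "prob_fused"}
        assert df["prob_fused"].between(0, 1).all()
        assert "GRU" in res.summary()
        res.save(tmp_path)
        loaded = VHDDetectorResults.load(tmp_path)
        df2 = loaded.predict(tiny_cohort, features=tiny_features)
        np.testing.assert_allclose(df2["prob_fused"], df["prob_fused"], atol=1e-12)


class TestCrossValidate:
    def test_partition_properties(self, tiny_cohort, tiny_features):
        pos = [p for p in tiny_cohort if p.significant][:5]
        neg = [p for p in tiny_cohort if not p.significant][:5]
        cohort = pos + neg  # balanced so 5 stratified folds are feasible
        grid = [(TINY, PreprocConfig())]
        out = cross_validate(cohort, grid, k=5, seed=1)
        folds = out["folds"]
        all_val = [i for _tr, va in folds for i in va]
        assert sorted(all_val) == list(range(10))  # every patient in exactly one fold
        for tr, va in folds:
            assert len(va) == 2
            assert not set(tr) & set(va)
        assert out["best_index"] == 0  # single-element grid returns that element
        assert len(out["oof_probs"]) == 10

    def test_invalid_k(self, tiny_cohort):
        with pytest.raises(ValueError):
            cross_validate(tiny_cohort[:4], [(TINY, PreprocConfig())], k=10)
        with pytest.raises(ValueError):
            cross_validate(tiny_cohort[:4], [(TINY, PreprocConfig())], k=1)
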