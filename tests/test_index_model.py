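"""Index training, selection, application and sub-classifier experiments."""

import numpy as np
import pandas as pd
import pytest

from methrisk import index_model, risk, synthetic
from methrisk.index_model import DegenerateModelError, IndexModel
from methrisk.synthetic import Effect, SimulationConfig

from conftest import SMALL_CS


def _meta(n_samples, n_cases):
    return pd.DataFrame({
        "sample_id": [f"S{i:04d}" for i in range(n_samples)],
        "type": ["control"] * (n_samples - n_cases) + ["case"] * n_cases,
        "ic": np.linspace(0, 1, n_samples),
        "age": np.full(n_samples, 50.0),
    })


class TestSplitDiscovery:
    def test_rounding_contract(self):
        meta = _meta(1198, 409)
        assign = index_model.split_discovery(meta, 2 / 3, seed=0)
        assert abs(assign.sum() - round(2 / 3 * 1198)) < 1

    def test_determinism(self):
        meta = _meta(100, 40)
        a1 = index_model.split_discovery(meta, 0.7, seed=3)
        a2 = index_model.split_discovery(meta, 0.7, seed=3)
        pd.testing.assert_series_equal(a1, a2)

    def test_training_frequency_over_seeds(self):
        """Each sample lands in training ~ 2/3 of the time (MC check)."""
        meta = _meta(60, 20)
        counts = np.zeros(60)
        for seed in range(100):
            counts += index_model.split_discovery(meta, 2 / 3, seed=seed).to_numpy()
        freq = counts / 100
        assert np.all(np.abs(freq - 2 / 3) < 0.2)
        assert abs(freq.mean() - 2 / 3) < 0.01

    def test_empty_group_error(self):
        meta = _meta(6, 1)
        with pytest.raises(ValueError):
            index_model.split_discovery(meta, 0.9, seed=1)


class TestTrainAndApply:
    def test_standardization_identity(self, pipeline_cohort, pipeline_split,
                                      pipeline_model):
        train_ids = pipeline_split[pipeline_split].index
        scores = index_model.apply_index(pipeline_model,
                                         pipeline_cohort.betas[train_ids])
        assert abs(scores.mean()) < 1e-8
        assert abs(scores.std(ddof=1) - 1) < 1e-8

    def test_strong_planted_effects_auc(self, pipeline_cohort,
                                        pipeline_meta_estimated,
                                        pipeline_split, pipeline_model):
        """Separable-by-construction cohort: held-out AUC > 0.95."""
        val_ids = pipeline_split[~pipeline_split].index
        scores = index_model.apply_index(pipeline_model,
                                         pipeline_cohort.betas[val_ids])
        y = (pipeline_meta_estimated.set_index("sample_id")
             .loc[val_ids, "type"] == "case").astype(int)
        auc, *_ = risk.auc_ci(scores.to_numpy(), y.to_numpy())
        assert auc > 0.95

    def test_null_cohort_auc_near_half(self):
        """No planted effects: held-out AUC distribution centred on 0.5."""
        aucs = []
        for seed in range(10):
            cfg = SimulationConfig(n_controls=80, n_cases=60, n_cpgs=200,
                                   seed=3000 + seed)
            ds = synthetic.generate_dataset(cfg)
            split = index_model.split_discovery(ds.meta, 2 / 3, seed=seed)
            ranked = pd.DataFrame({"cpg_id": ds.betas.index[:80]})
            model = index_model.train_index(
                ds.betas[split[split].index], ds.meta, ranked, 80,
                penalty="ridge", seed=seed, Cs=np.logspace(-2, 2, 5), cv=5)
            val = split[~split].index
            scores = index_model.apply_index(model, ds.betas[val])
            y = (ds.meta.set_index("sample_id").loc[val, "type"] == "case")
            auc, *_ = risk.auc_ci(scores.to_numpy(), y.to_numpy().astype(int))
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_exclusion_noop_cases(self, pipeline_cohort, pipeline_split,
                                  pipeline_model):
        val_ids = pipeline_split[~pipeline_split].index
        betas = pipeline_cohort.betas[val_ids]
        plain = index_model.apply_index(pipeline_model, betas)
        empty = index_model.apply_index(pipeline_model, betas, exclude=set())
        pd.testing.assert_series_equal(plain, empty)
        zero_w = {c for c, w in zip(pipeline_model.cpgs, pipeline_model.weights)
                  if w == 0}
        if zero_w:
            same = index_model.apply_index(pipeline_model, betas, exclude=zero_w)
            pd.testing.assert_series_equal(plain, same)

    def test_exclusion_matches_rescoring_oracle(self, pipeline_cohort,
                                                pipeline_split, pipeline_model):
        """Excluding CpGs equals re-scoring with their weights zeroed."""
        rng = np.random.default_rng(12)
        m = pipeline_model
        drop = set(rng.choice(m.cpgs, size=len(m.cpgs) // 10, replace=False))
        val_ids = pipeline_split[~pipeline_split].index
        betas = pipeline_cohort.betas[val_ids]
        excluded = index_model.apply_index(m, betas, exclude=drop)
        w0 = np.where([c in drop for c in m.cpgs], 0.0, m.weights)
        oracle = (betas.loc[m.cpgs].to_numpy().T @ w0 - m.mu) / m.sigma
        assert np.allclose(excluded.to_numpy(), oracle, atol=1e-12)

    def test_missing_cpgs_beyond_tolerance_error(self, pipeline_cohort,
                                                 pipeline_model):
        betas = pipeline_cohort.betas.drop(index=pipeline_model.cpgs[:50])
        with pytest.raises(ValueError, match="missing"):
            index_model.apply_index(pipeline_model, betas)

    def test_monotone_weight_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        w = rng.normal(0, 1, 5)
        tm = rng.uniform(0.2, 0.8, 5)
        betas = pd.DataFrame(rng.uniform(0, 1, (5, 8)),
                             index=[f"cg{j}" for j in range(5)],
                             columns=[f"S{i}" for i in range(8)])
        kw = dict(cpgs=list(betas.index), intercept=0.0, train_means=tm,
                  penalty="ridge", C=1.0, n=5)
        m1 = IndexModel(weights=w, mu=float(w @ tm), sigma=2.0, **kw)
        c = 3.7
        m2 = IndexModel(weights=c * w, mu=float(c * w @ tm), sigma=c * 2.0, **kw)
        s1 = index_model.apply_index(m1, betas)
        s2 = index_model.apply_index(m2, betas)
        assert np.allclose(s1, s2, atol=1e-12)

    def test_auc_invariant_to_standardization(self, pipeline_cohort,
                                              pipeline_meta_estimated,
                                              pipeline_split, pipeline_model):
        val_ids = pipeline_split[~pipeline_split].index
        betas = pipeline_cohort.betas[val_ids]
        y = (pipeline_meta_estimated.set_index("sample_id")
             .loc[val_ids, "type"] == "case").astype(int).to_numpy()
        std = index_model.apply_index(pipeline_model, betas).to_numpy()
        raw = betas.loc[pipeline_model.cpgs].to_numpy().T @ pipeline_model.weights
        a1, *_ = risk.auc_ci(std, y)
        a2, *_ = risk.auc_ci(raw, y)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_serialization_roundtrip(self, pipeline_model, tmp_path):
        path = tmp_path / "model.json"
        pipeline_model.to_json(path)
        loaded = IndexModel.from_json(path)
        assert loaded.cpgs == pipeline_model.cpgs
        assert np.allclose(loaded.weights, pipeline_model.weights)
        assert loaded.mu == pipeline_model.mu
        assert loaded.sigma == pipeline_model.sigma


class TestSelectN:
    def test_single_grid_value_chosen(self, pipeline_cohort,
                                      pipeline_meta_estimated,
                                      pipeline_ranked, pipeline_split):
        curve, final = index_model.select_n(
            pipeline_cohort.betas, pipeline_meta_estimated, pipeline_ranked,
            pipeline_split, grid=[150], penalties=("ridge",),
            seed=1, Cs=SMALL_CS, cv=5)
        assert final.provenance["selected_n"] == 150
        assert final.provenance["hyperparameters_frozen"]
        assert len(curve) == 1

    def test_signal_concentrated_prefers_small_n(self):
        """Signal confined to top-ranked CpGs: small n wins the curve."""
        cfg = SimulationConfig(
            n_controls=200, n_cases=120, n_cpgs=400,
            effects=[Effect(range(60), "epithelial", 0.15)], seed=55)
        ds = synthetic.generate_dataset(cfg)
        from methrisk import dmp
        deltas = dmp.estimate_celltype_deltabeta(ds.betas, ds.meta)
        ranked = dmp.rank_interleave(deltas)
        split = index_model.split_discovery(ds.meta, 2 / 3, seed=2)
        curve, final = index_model.select_n(
            ds.betas, ds.meta, ranked, split, grid=[150, 400],
            penalties=("ridge",), seed=2, Cs=np.logspace(-2, 2, 5), cv=5)
        chosen = curve.loc[curve["auc"].idxmax()]
        assert final.provenance["selected_n"] == chosen["n"]
        assert chosen["auc"] == curve["auc"].max()

    def test_reproducible_under_seed(self, pipeline_cohort,
                                     pipeline_meta_estimated,
                                     pipeline_ranked, pipeline_split):
        args = (pipeline_cohort.betas, pipeline_meta_estimated,
                pipeline_ranked, pipeline_split)
        kw = dict(grid=[100], penalties=("ridge",), seed=9, Cs=SMALL_CS, cv=5)
        c1, m1 = index_model.select_n(*args, **kw)
        c2, m2 = index_model.select_n(*args, **kw)
        pd.testing.assert_frame_equal(c1, c2)
        assert np.allclose(m1.weights, m2.weights)


class TestSubclassifiers:
    def test_bins_partition_model_cpgs(self, pipeline_cohort,
                                       pipeline_meta_estimated,
                                       pipeline_split, pipeline_model):
        res = index_model.subclassifier_experiment(
            pipeline_cohort.betas, pipeline_meta_estimated, pipeline_model,
            pipeline_split, mode="bins", bin_size=100, cv=5, Cs=SMALL_CS)
        assert res["n_cpgs"].sum() == len(pipeline_model.cpgs)

    def test_top_bin_beats_last_bin(self, pipeline_cohort,
                                    pipeline_meta_estimated,
                                    pipeline_split, pipeline_model):
        """Signal is concentrated in the top-weighted CpGs by construction."""
        res = index_model.subclassifier_experiment(
            pipeline_cohort.betas, pipeline_meta_estimated, pipeline_model,
            pipeline_split, mode="bins", bin_size=100, cv=5, Cs=SMALL_CS)
        assert res["auc"].iloc[0] >= res["auc"].iloc[-1]

    def test_top_n_all_matches_full_model(self, pipeline_cohort,
                                          pipeline_meta_estimated,
                                          pipeline_split, pipeline_model):
        res = index_model.subclassifier_experiment(
            pipeline_cohort.betas, pipeline_meta_estimated, pipeline_model,
            pipeline_split, mode="top-n", ns=(len(pipeline_model.cpgs),),
            cv=5, Cs=SMALL_CS)
        val_ids = pipeline_split[~pipeline_split].index
        scores = index_model.apply_index(pipeline_model,
                                         pipeline_cohort.betas[val_ids])
        y = (pipeline_meta_estimated.set_index("sample_id")
             .loc[val_ids, "type"] == "case").astype(int).to_numpy()
        full_auc, *_ = risk.auc_ci(scores.to_numpy(), y)
        assert abs(res["auc"].iloc[0] - full_auc) < 0.05


class TestTissueIndex:
    def test_zero_k_rejected(self, pipeline_cohort, pipeline_meta_estimated):
        with pytest.raises(ValueError):
            index_model.train_tissue_index(pipeline_cohort.betas,
                                           pipeline_meta_estimated, k=0)

    def test_planted_tissue_signal(self):
        """Large-effect two-class tissue data: lasso picks useful CpGs and
        separates the test split."""
        cfg = SimulationConfig(
            n_controls=120, n_cases=120, n_cpgs=400,
            rho_distribution=("constant", 0.0),
            effects=[Effect(range(50), "epithelial", 0.25)], seed=31)
        ds = synthetic.generate_dataset(cfg)
        model, report = index_model.train_tissue_index(
            ds.betas, ds.meta, k=50, seed=4, Cs=np.logspace(-2, 2, 5), cv=5)
        assert report["test_auc"] > 0.95
        assert report["n_selected"] <= report["n_candidates"]
        planted = set(ds.betas.index[:50])
        selected = {c for c, w in zip(model.cpgs, model.weights) if w != 0}
        assert selected <= planted

    def test_null_transfer(self):
        """A tissue model applied to an unrelated cohort with no planted
        tumour signal scores at chance."""
        cfg = SimulationConfig(
            n_controls=120, n_cases=120, n_cpgs=400,
            rho_distribution=("constant", 0.0),
            effects=[Effect(range(50), "epithelial", 0.25)], seed=31)
        ds = synthetic.generate_dataset(cfg)
        model, _ = index_model.train_tissue_index(
            ds.betas, ds.meta, k=50, seed=4, Cs=np.logspace(-2, 2, 5), cv=5)
        null_cfg = SimulationConfig(n_controls=150, n_cases=150, n_cpgs=400,
                                    seed=99)
        null_ds = synthetic.generate_dataset(null_cfg)
        scores = index_model.apply_index(model, null_ds.betas)
        y = (null_ds.meta["type"] == "case").astype(int).to_numpy()
        auc, *_ = risk.auc_ci(scores.to_numpy(), y)
        assert abs(auc - 0.5) < 0.12

    def test_lasso_all_zero_weights_raises(self):
        """Heavy lasso penalty on pure noise: degenerate model refused."""
        cfg = SimulationConfig(n_controls=40, n_cases=40, n_cpgs=50, seed=17)
        ds = synthetic.generate_dataset(cfg)
        ranked = pd.DataFrame({"cpg_id": ds.betas.index})
        with pytest.raises(DegenerateModelError):
            index_model.train_index(ds.betas, ds.meta, ranked, 50,
                                    penalty="lasso", C=1e-6)
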