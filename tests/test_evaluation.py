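import math

import numpy as np
import pytest

import dmsfill as df
from dmsfill.evaluation import SplitError, _GRANULARITY


@pytest.fixture(scope="module")
def corpus():
    spec = df.SyntheticSpec(n_domains=5, length_range=(15, 25), seed=4)
    ds, truth = df.simulate(spec)
    nds = df.normalize_scores(ds, df.estimate_all_baselines(ds))
    return nds, truth


def _observed_keys(nds):
    return {r.key for r in nds.substitution_records()}


class TestMakeSplit:
    def test_lopo_series_contract(self, corpus):
        nds, _ = corpus
        plans = df.make_split(nds, "lopo_series")
        assert len(plans) == len(nds.domains)
        for plan in plans:
            test_proteins = {k.protein_id for k in plan.test_keys}
            assert len(test_proteins) == 1
            assert test_proteins.isdisjoint(
                {k.protein_id for k in plan.train_keys})
        all_test = set().union(*({k for k in p.test_keys} for p in plans))
        assert all_test == _observed_keys(nds)

    def test_random_ratio_counts(self):
        spec = df.SyntheticSpec(n_domains=1, length_range=(10, 10),
                                observed_fraction=100 / 190, seed=6)
        ds, _ = df.simulate(spec)
        nds = df.normalize_scores(ds, df.estimate_all_baselines(ds))
        n = len(nds.substitution_records())
        assert n == 100
        plan = df.make_split(nds, "random_ratio", {"ratio": 0.8}, seed=1)
        assert len(plan.train_keys) == 80 and len(plan.test_keys) == 20
        plan = df.make_split(nds, "random_ratio", {"ratio": 0.15}, seed=1)
        assert len(plan.train_keys) == 15 and len(plan.test_keys) == 85

    def test_random_ratio_is_per_protein(self, corpus):
        nds, _ = corpus
        plan = df.make_split(nds, "random_ratio", {"ratio": 0.8}, seed=2)
        for pid in nds.domains:
            n = sum(1 for r in nds.substitution_records()
                    if r.key.protein_id == pid)
            n_train = sum(1 for k in plan.train_keys if k.protein_id == pid)
            assert n_train == min(n - 1, max(1, math.floor(0.8 * n + 0.5)))

    def test_lposo_holds_out_whole_positions(self, corpus):
        nds, _ = corpus
        plan = df.make_split(nds, "lposo_ratio", {"ratio": 0.8}, seed=2)
        tr = {(k.protein_id, k.position) for k in plan.train_keys}
        te = {(k.protein_id, k.position) for k in plan.test_keys}
        assert tr.isdisjoint(te)

    def test_lovaro_enumerates_each_variant_once(self, corpus):
        nds, _ = corpus
        plans = df.make_split(nds, "lovaro_series")
        keys = _observed_keys(nds)
        assert len(plans) == len(keys)
        assert all(len(p.test_keys) == 1 for p in plans)
        assert {p.test_keys[0] for p in plans} == keys

    def test_loposo_and_lovaro_cover_same_keys(self, corpus):
        nds, _ = corpus
        lop = df.make_split(nds, "loposo_series")
        lov = df.make_split(nds, "lovaro_series")
        union = lambda plans: set().union(*(set(p.test_keys) for p in plans))
        assert union(lop) == union(lov)

    def test_series_test_sizes_partition_dataset(self, corpus):
        nds, _ = corpus
        n = len(_observed_keys(nds))
        for strategy in ("loposo_series", "lovaro_series", "lopo_series"):
            plans = df.make_split(nds, strategy)
            assert sum(len(p.test_keys) for p in plans) == n

    def test_snv_split_direction(self, corpus):
        nds, _ = corpus
        plan = df.make_split(nds, "snv_split")
        assert all(df.snv_indicator(k.wt_aa, k.var_aa) == 1
                   for k in plan.train_keys)
        assert all(df.snv_indicator(k.wt_aa, k.var_aa) == 0
                   for k in plan.test_keys)
        assert set(plan.train_keys) | set(plan.test_keys) == _observed_keys(nds)

    def test_family_unique_keeps_one_domain_per_family(self, corpus):
        nds, truth = corpus
        plan = df.make_split(nds, "family_unique", {"ratio": 0.3}, seed=0)
        used = {k.protein_id for k in plan.train_keys + plan.test_keys}
        fams = [nds.domains[p].family_id for p in used]
        assert len(fams) == len(set(fams))
        train_fams = {nds.domains[k.protein_id].family_id
                      for k in plan.train_keys}
        test_fams = {nds.domains[k.protein_id].family_id
                     for k in plan.test_keys}
        assert train_fams.isdisjoint(test_fams)

    def test_family_unique_requires_family_ids(self, corpus):
        nds, _ = corpus
        stripped = df.DMSDataset(
            domains={p: df.DomainEntry(p, d.sequence, wt_score=d.wt_score)
                     for p, d in nds.domains.items()},
            records=list(nds.records))
        with pytest.raises(SplitError, match="family_id"):
            df.make_split(stripped, "family_unique")

    @pytest.mark.parametrize("ratio", [0.0, 1.0, -0.2, 1.7])
    def test_bad_ratios_rejected(self, corpus, ratio):
        nds, _ = corpus
        with pytest.raises(SplitError, match="ratio"):
            df.make_split(nds, "random_ratio", {"ratio": ratio})

    def test_same_seed_same_split(self, corpus):
        nds, _ = corpus
        a = df.make_split(nds, "random_ratio", {"ratio": 0.8}, seed=9)
        b = df.make_split(nds, "random_ratio", {"ratio": 0.8}, seed=9)
        assert a.train_keys == b.train_keys and a.test_keys == b.test_keys


class TestVerifySplit:
    def test_checker_catches_manufactured_leak(self, corpus):
        nds, _ = corpus
        plan = df.make_split(nds, "leave_protein_out", seed=0)
        leaky = df.SplitPlan(
            "leave_protein_out", plan.params,
            plan.train_keys + (plan.test_keys[0],), plan.test_keys[1:])
        with pytest.raises(SplitError, match="leakage"):
            df.verify_split(leaky, nds)

    def test_checker_catches_position_leak(self, corpus):
        nds, _ = corpus
        plan = df.make_split(nds, "lposo_ratio", {"ratio": 0.8}, seed=0)
        # move one test variant into train: its position now straddles both
        k = plan.test_keys[0]
        same_pos = [kk for kk in plan.test_keys
                    if (kk.protein_id, kk.position) == (k.protein_id, k.position)]
        if len(same_pos) < 2:
            pytest.skip("need a test position with >= 2 variants")
        leaky = df.SplitPlan("lposo_ratio", plan.params,
                             plan.train_keys + (same_pos[0],),
                             tuple(kk for kk in plan.test_keys
                                   if kk != same_pos[0]))
        with pytest.raises(SplitError, match="position leakage"):
            df.verify_split(leaky, nds)

    def test_all_strategies_pass_their_own_checker(self, corpus):
        nds, _ = corpus
        for strategy in _GRANULARITY:
            plans = df.make_split(nds, strategy, seed=1)
            if isinstance(plans, df.SplitPlan):
                plans = [plans]
            for p in plans:
                df.verify_split(p, nds)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        rep = df.compute_metrics([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert rep.rmse == 0 and rep.mae == 0
        assert rep.r2 == pytest.approx(1.0) and rep.pearson_r == pytest.approx(1.0)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([0.0, 0.5, 1.0, 0.3])
        rep = df.compute_metrics(y, np.full(4, y.mean()))
        assert rep.r2 == pytest.approx(0.0)
        assert "constant_predictions" in rep.flags

    def test_anticorrelated_hand_example(self):
        rep = df.compute_metrics([0.0, 1.0], [1.0, 0.0])
        assert rep.pearson_r == pytest.approx(-1.0)
        assert rep.rmse == pytest.approx(1.0)

    def test_matches_textbook_formulas_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.standard_normal(40)
            p = y + rng.standard_normal(40) * 0.5
            rep = df.compute_metrics(y, p)
            # independent brute-force oracle
            rmse = (sum((a - b) ** 2 for a, b in zip(y, p)) / len(y)) ** 0.5
            mae = sum(abs(a - b) for a, b in zip(y, p)) / len(y)
            ybar = sum(y) / len(y)
            r2 = 1 - sum((a - b) ** 2 for a, b in zip(y, p)) / sum(
                (a - ybar) ** 2 for a in y)
            my = sum(y) / len(y); mp = sum(p) / len(p)
            cov = sum((a - my) * (b - mp) for a, b in zip(y, p))
            r = cov / (sum((a - my) ** 2 for a in y) ** 0.5
                       * sum((b - mp) ** 2 for b in p) ** 0.5)
            assert rep.rmse == pytest.approx(rmse, abs=1e-12)
            assert rep.mae == pytest.approx(mae, abs=1e-12)
            assert rep.r2 == pytest.approx(r2, abs=1e-12)
            assert rep.pearson_r == pytest.approx(r, abs=1e-12)

    def test_zero_variance_truth_flags_undefined_r(self):
        with pytest.warns(UserWarning, match="zero variance"):
            rep = df.compute_metrics([1.0, 1.0, 1.0], [0.9, 1.1, 1.0])
        assert math.isnan(rep.r2) and math.isnan(rep.pearson_r)
        assert rep.flags["zero_variance_truth"]


class TestRunProtocol:
    def test_partition_conservation_and_report_fields(self, corpus):
        nds, _ = corpus
        reports, errors = df.run_protocol(
            nds, "random_ratio", "mean_only",
            strategy_params={"ratio": 0.8}, seed=3, max_rounds=60)
        rep = reports[0]
        n = len(nds.substitution_records())
        assert rep.n_train + rep.n_test == n
        assert rep.strategy == "random_ratio" and rep.preset == "mean_only"
        assert len(errors) == rep.n_test
        assert set(errors.columns) >= {"observed", "predicted", "abs_error",
                                       "sq_error", "pct_error"}

    def test_within_protein_prior_flagged_for_protein_holdout(self, corpus):
        nds, _ = corpus
        reports, _ = df.run_protocol(nds, "leave_protein_out", "mean_only",
                                     seed=3, max_rounds=60)
        assert reports[0].flags.get("within_protein_prior")

    def test_snv_protocol_drops_the_indicator(self, corpus):
        nds, truth = corpus
        cfg = df.FeatureSetConfig(mean_dms=True, snv=True)
        reports, _ = df.run_protocol(nds, "snv_split", cfg, seed=0,
                                     max_rounds=60)
        assert reports[0].n_test > 0  # ran without the indicator column

    def test_noiseless_lovaro_recovers_scores(self):
        spec = df.SyntheticSpec(n_domains=1, length_range=(10, 10),
                                noise_sd=0.0, eve_noise_sd=0.0,
                                observed_fraction=0.4, seed=8)
        ds, truth = df.simulate(spec)
        nds = df.normalize_scores(ds, df.estimate_all_baselines(ds))
        archive = df.simulate_embeddings(nds, truth, dim=8,
                                         signal_fraction=1.0, seed=8)
        reports, errors = df.run_protocol(nds, "lovaro_series",
                                          "esm_plus_mean", seed=8,
                                          embeddings=archive, max_rounds=150)
        assert errors["sq_error"].median() < 0.02


class TestMaskedEval:
    def _model(self, corpus):
        nds, truth = corpus
        cfg = df.FeatureSetConfig.preset("mean_only")
        priors = {"mean_dms": df.positional_mean(nds)}
        fm = df.assemble_features(nds, cfg, priors=priors)
        y = np.array([r.norm_score for r in nds.substitution_records()])
        return df.train(fm, y, seed=0, max_rounds=60), cfg

    def test_exact_mask_counts_and_determinism(self, corpus):
        nds, _ = corpus
        model, cfg = self._model(corpus)
        n = len(nds.substitution_records())
        rep1 = df.masked_external_eval(nds, model, cfg, 0.3, seed=5)
        rep2 = df.masked_external_eval(nds, model, cfg, 0.3, seed=5)
        assert rep1.n_test == round(0.3 * n)
        assert rep1.n_train == n - rep1.n_test
        assert rep1.rmse == rep2.rmse and rep1.r2 == rep2.r2

    def test_bad_fraction_rejected(self, corpus):
        nds, _ = corpus
        model, cfg = self._model(corpus)
        with pytest.raises(ValueError):
            df.masked_external_eval(nds, model, cfg, 1.5, seed=0)


class TestZeroShot:
    def test_prior_preset_refused(self, corpus):
        nds, _ = corpus
        cfg = df.FeatureSetConfig.preset("esm_plus_mean")
        with pytest.raises(ValueError, match="zero-shot"):
            df.zero_shot_eval(nds, model=None, config=cfg)

    def test_zero_shot_scores_unseen_protein(self, corpus):
        nds, truth = corpus
        archive = df.simulate_embeddings(nds, truth, dim=8,
                                         signal_fraction=0.8, seed=4)
        cfg = df.FeatureSetConfig(wt_esm=True, var_esm=True, sm=True, snv=True)
        plan = df.make_split(nds, "leave_protein_out", seed=4)
        fm = df.assemble_features(nds, cfg, embeddings=archive,
                                  keys=plan.train_keys)
        score_of = {r.key: r.norm_score for r in nds.substitution_records()}
        y = np.array([score_of[k] for k in plan.train_keys])
        model = df.train(fm, y, seed=0, max_rounds=100)
        held = df.DMSDataset(
            domains=dict(nds.domains),
            records=[r for r in nds.records
                     if r.key.protein_id in {k.protein_id
                                             for k in plan.test_keys}])
        rep = df.zero_shot_eval(held, model, cfg, embeddings=archive)
        assert rep.strategy == "zero_shot"
        assert math.isfinite(rep.rmse) and math.isfinite(rep.r2)
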