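import warnings

import numpy as np
import pandas as pd
import pytest

from aips import (
    ClassLabel,
    ExpressionMatrix,
    GeneSignature,
    RoiConfig,
    SignatureSpec,
    SimConfig,
    simulate_multidataset,
)
from aips.train import (
    CLASSES,
    AipsModel,
    AipsTrainer,
    GoldStandard,
    PairRule,
    RuleMiner,
    build_gold_standard,
    compute_weights,
    filter_models,
    fit_naive_bayes,
    load_models,
    save_models,
    score_rules,
    select_k,
    select_top_k,
)
from aips.roi import roi_assign
from aips.predict import predict_batch, predict_single


def _gold_from_frame(entries: pd.DataFrame) -> GoldStandard:
    per_sample = entries[["sample_id", "dataset_id"]].drop_duplicates()
    weights = compute_weights(
        pd.Series(per_sample["dataset_id"].to_numpy(),
                  index=per_sample["sample_id"].to_numpy())
    )
    return GoldStandard(entries=entries, weights=weights)


class TestComputeWeights:
    def test_two_unequal_datasets(self):
        ds = pd.Series(["d1", "d1", "d2"] + ["d2"] * 7,
                       index=[f"s{i}" for i in range(10)])
        w = compute_weights(ds)
        assert w.loc[("d1", "s0")] == pytest.approx(0.25)
        assert w.loc[("d2", "s3")] == pytest.approx(1 / (2 * 8))
        assert w.groupby("dataset_id").sum().tolist() == pytest.approx([0.5, 0.5])
        assert w.sum() == pytest.approx(1.0)

    def test_single_dataset_uniform(self):
        w = compute_weights(pd.Series(["d"] * 4, index=list("abcd")))
        np.testing.assert_allclose(w, 0.25)

    def test_equal_sized_datasets_equal_weights(self):
        ds = pd.Series(["d1"] * 5 + ["d2"] * 5, index=[f"s{i}" for i in range(10)])
        assert compute_weights(ds).nunique() == 1


@pytest.fixture(scope="module")
def tiny_training():
    """Two 60-sample datasets with one strongly planted 10-gene signature."""
    cfg = SimConfig(
        n_samples=60, n_genes=40,
        signatures=[SignatureSpec("PLANT", k=10, delta=3.0)],
        seed=17,
    )
    ds = simulate_multidataset(cfg, 2)
    datasets = {k: v[0] for k, v in ds.items()}
    sig = ds["D0"][1].signatures["PLANT"]
    roi_cfg = RoiConfig(n_trials=2000, seed=4)
    gold = build_gold_standard(datasets, [sig], roi_cfg)
    return datasets, sig, gold, roi_cfg


class TestGoldStandard:
    def test_single_dataset_reduces_to_roi(self, tiny_training):
        datasets, sig, _, roi_cfg = tiny_training
        one = {"D0": datasets["D0"]}
        gold = build_gold_standard(one, [sig], roi_cfg)
        roi = roi_assign(datasets["D0"], sig, roi_cfg)
        sub = gold.labels_for("PLANT").set_index("sample_id")["label"]
        assert (sub.loc[roi.labels.index] == roi.labels).all()

    def test_missing_signature_omitted_not_fatal(self, tiny_training):
        datasets, sig, _, roi_cfg = tiny_training
        absent = GeneSignature("ABSENT", up_genes={"zz1", "zz2", "zz3", "zz4", "zz5"})
        gold = build_gold_standard(datasets, [sig, absent], roi_cfg)
        assert gold.signature_ids() == ["PLANT"]

    def test_weights_balance_datasets(self, tiny_training):
        _, _, gold, _ = tiny_training
        per_ds = gold.weights.groupby("dataset_id").sum()
        assert per_ds.nunique() == 1
        assert gold.weights.sum() == pytest.approx(1.0)


class TestScoreRules:
    def test_perfect_and_null_rule_scores(self):
        # hand-built gold standard on a 3-gene, 12-sample single dataset
        rng = np.random.default_rng(1)
        labels = np.array([ClassLabel.HIGH] * 4 + [ClassLabel.LOW] * 4
                          + [ClassLabel.INDEPENDENT] * 4, dtype=object)
        x = np.vstack([
            np.where([l == ClassLabel.HIGH for l in labels], 5.0, 1.0),  # gX
            np.full(12, 3.0),                                            # gY
            rng.uniform(0, 10, 12),                                      # gZ
        ])
        expr = ExpressionMatrix(pd.DataFrame(
            x, index=["gX", "gY", "gZ"], columns=[f"s{i}" for i in range(12)]))
        entries = pd.DataFrame({
            "sample_id": expr.sample_ids, "dataset_id": "d",
            "signature_id": "S", "label": labels,
        })
        gold = _gold_from_frame(entries)
        ranked = score_rules({"d": expr}, gold, "S", expr.gene_ids, n_top=6)
        # rule gX > gY is true exactly on class high -> score 1 for high
        top_high = ranked[ClassLabel.HIGH][0]
        assert (top_high.gene_x, top_high.gene_y) == ("gX", "gY")
        assert top_high.score == pytest.approx(1.0)

    def test_top_rule_matches_brute_force(self):
        rng = np.random.default_rng(9)
        n, genes = 30, [f"g{i}" for i in range(6)]
        x = rng.uniform(1, 10, size=(6, n))
        labels = np.array(
            [ClassLabel.LOW] * 10 + [ClassLabel.INDEPENDENT] * 10
            + [ClassLabel.HIGH] * 10, dtype=object)
        expr = ExpressionMatrix(pd.DataFrame(
            x, index=genes, columns=[f"s{i}" for i in range(n)]))
        entries = pd.DataFrame({"sample_id": expr.sample_ids, "dataset_id": "d",
                                "signature_id": "S", "label": labels})
        gold = _gold_from_frame(entries)
        ranked = score_rules({"d": expr}, gold, "S", genes, n_top=30)

        # independent brute force over all ordered pairs and classes
        def brute(cls):
            best, best_score = None, -np.inf
            for i, gx in enumerate(genes):
                for j, gy in enumerate(genes):
                    if i == j:
                        continue
                    truth = x[i] > x[j]
                    inm = np.array([l == cls for l in labels])
                    s = truth[inm].mean() - truth[~inm].mean()
                    if s > best_score:
                        best, best_score = (gx, gy), s
            return best, best_score

        for cls in CLASSES:
            (bx, by), bscore = brute(cls)
            top = ranked[cls][0]
            assert top.score == pytest.approx(bscore, abs=1e-6)
            # the specific pair may tie; scores must match exactly
            truth_top = x[genes.index(top.gene_x)] > x[genes.index(top.gene_y)]
            truth_b = x[genes.index(bx)] > x[genes.index(by)]
            inm = np.array([l == cls for l in labels])
            assert (truth_top[inm].mean() - truth_top[~inm].mean()
                    == pytest.approx(bscore, abs=1e-6))

    def test_scores_invariant_to_per_sample_monotone_transform(self, tiny_training):
        datasets, sig, gold, _ = tiny_training
        universe = datasets["D0"].gene_ids
        base = score_rules(datasets, gold, "PLANT", universe, n_top=5)
        warped = {
            k: ExpressionMatrix(np.log1p(v.data) ** 3)
            for k, v in datasets.items()
        }
        again = score_rules(warped, gold, "PLANT", universe, n_top=5)
        for cls in CLASSES:
            assert [(r.gene_x, r.gene_y) for r in base[cls]] == [
                (r.gene_x, r.gene_y) for r in again[cls]
            ]
            np.testing.assert_allclose(
                [r.score for r in base[cls]], [r.score for r in again[cls]],
                atol=1e-6,
            )

    def test_weighted_scores_invariant_to_dataset_duplication(self, tiny_training):
        datasets, sig, gold, roi_cfg = tiny_training
        universe = datasets["D0"].gene_ids
        base = score_rules(datasets, gold, "PLANT", universe, n_top=5)
        # duplicate D1 as a third dataset with renamed samples
        dup = datasets["D1"].data.copy()
        dup.columns = [c + "_dup" for c in dup.columns]
        datasets3 = dict(datasets, D2=ExpressionMatrix(dup))
        gold3 = build_gold_standard(datasets3, [sig], roi_cfg)
        again = score_rules(datasets3, gold3, "PLANT", universe, n_top=5)
        for cls in CLASSES:
            np.testing.assert_allclose(
                [r.score for r in base[cls]], [r.score for r in again[cls]],
                atol=0.05,
            )


class TestSelectTopK:
    def test_interleaves_classes_and_dedups(self):
        mk = lambda x, y, c, s: PairRule(x, y, c, s)
        ranked = {
            ClassLabel.HIGH: [mk("a", "b", ClassLabel.HIGH, 3.0),
                              mk("c", "d", ClassLabel.HIGH, 2.0)],
            ClassLabel.LOW: [mk("a", "b", ClassLabel.LOW, 2.5),
                             mk("e", "f", ClassLabel.LOW, 2.0)],
            ClassLabel.INDEPENDENT: [mk("g", "h", ClassLabel.INDEPENDENT, 1.0)],
        }
        rules = select_top_k(ranked, 4)
        pairs = [(r.gene_x, r.gene_y) for r in rules]
        # high first, then low (skipping the duplicated (a,b)), then independent
        assert pairs == [("a", "b"), ("e", "f"), ("g", "h"), ("c", "d")]
        assert len(set(pairs)) == len(pairs)


class TestFitNaiveBayes:
    def test_smoothed_conditional_arithmetic(self):
        # single rule true for all 10 high, false for 10 low and 10 independent
        labels = np.array([ClassLabel.HIGH] * 10 + [ClassLabel.LOW] * 10
                          + [ClassLabel.INDEPENDENT] * 10, dtype=object)
        x = np.vstack([
            np.where([l == ClassLabel.HIGH for l in labels], 9.0, 1.0),
            np.full(30, 5.0),
        ])
        expr = ExpressionMatrix(pd.DataFrame(
            x, index=["gX", "gY"], columns=[f"s{i}" for i in range(30)]))
        entries = pd.DataFrame({"sample_id": expr.sample_ids, "dataset_id": "d",
                                "signature_id": "S", "label": labels})
        gold = _gold_from_frame(entries)
        rule = PairRule("gX", "gY", ClassLabel.HIGH)
        model = fit_naive_bayes([rule], {"d": expr}, gold, "S")
        j_high = CLASSES.index(ClassLabel.HIGH)
        j_low = CLASSES.index(ClassLabel.LOW)
        assert model.cond_prob[0, j_high] == pytest.approx(11 / 12)
        assert model.cond_prob[0, j_low] == pytest.approx(1 / 12)
        np.testing.assert_allclose(model.priors, 1 / 3)

    def test_serialization_round_trip_preserves_predictions(self, tmp_path,
                                                            tiny_training):
        datasets, sig, gold, _ = tiny_training
        universe = datasets["D0"].gene_ids
        ranked = score_rules(datasets, gold, "PLANT", universe, n_top=10)
        model = fit_naive_bayes(select_top_k(ranked, 8), datasets, gold, "PLANT")
        path = tmp_path / "models.json"
        save_models([model], path)
        (back,) = load_models(path)
        rng = np.random.default_rng(0)
        genes = universe
        for _ in range(100):
            profile = pd.Series(rng.uniform(1, 100, len(genes)), index=genes)
            a = predict_single(model, profile)
            b = predict_single(back, profile)
            assert a.label == b.label
            assert a.posteriors == b.posteriors


class TestSelectK:
    def test_perfect_rule_ties_break_to_smallest_k(self):
        rng = np.random.default_rng(3)
        n = 60
        labels = np.array([ClassLabel.LOW] * 20 + [ClassLabel.INDEPENDENT] * 20
                          + [ClassLabel.HIGH] * 20, dtype=object)
        # gA/gB and gC/gB each separate all three classes perfectly by ordering
        a = np.r_[np.full(20, 1.0), np.full(20, 5.0), np.full(20, 9.0)]
        x = np.vstack([a + rng.uniform(-0.1, 0.1, n), np.full(n, 5.0),
                       a + rng.uniform(-0.1, 0.1, n)])
        expr = ExpressionMatrix(pd.DataFrame(
            x, index=["gA", "gB", "gC"], columns=[f"s{i}" for i in range(n)]))
        entries = pd.DataFrame({"sample_id": expr.sample_ids, "dataset_id": "d",
                                "signature_id": "S", "label": labels})
        gold = _gold_from_frame(entries)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k, cv = select_k({"d": expr}, gold, "S", expr.gene_ids,
                             k_grid=[2, 4, 6], folds=5, seed=1)
        assert k == 2
        assert cv[2] == pytest.approx(max(cv.values()))

    def test_noise_rules_give_near_zero_cv_kappa(self):
        rng = np.random.default_rng(4)
        n = 90
        labels = np.array(rng.choice(CLASSES, n), dtype=object)
        x = rng.uniform(1, 10, size=(8, n))
        expr = ExpressionMatrix(pd.DataFrame(
            x, index=[f"g{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(n)]))
        entries = pd.DataFrame({"sample_id": expr.sample_ids, "dataset_id": "d",
                                "signature_id": "S", "label": labels})
        gold = _gold_from_frame(entries)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, cv = select_k({"d": expr}, gold, "S", expr.gene_ids,
                             k_grid=[1, 5, 10], folds=5, seed=2)
        assert max(cv.values()) < 0.35


class TestFilterModels:
    def test_planted_retained_noise_rejected(self, tiny_training):
        datasets, sig, gold, roi_cfg = tiny_training
        universe = datasets["D0"].gene_ids
        ranked = score_rules(datasets, gold, "PLANT", universe, n_top=20)
        good = fit_naive_bayes(select_top_k(ranked, 10), datasets, gold, "PLANT")
        # uninformative model: every rule's conditional is 0.5 for every class
        bad = AipsModel("PLANT", good.rules, np.full_like(good.cond_prob, 0.5),
                        good.priors, good.k)
        retained = filter_models([good, bad], datasets, gold, alpha=0.05)
        assert good in retained
        assert bad not in retained
        assert good.retained and not bad.retained
        assert set(good.kappa_by_dataset) == set(datasets)


class TestTrainerEndToEnd:
    def test_planted_models_recovered_and_validated(self):
        """Multi-dataset training recovers planted signatures; held-out kappa
        is significantly positive; noise signatures never reach a model."""
        specs = [SignatureSpec("P1", k=15, delta=3.0),
                 SignatureSpec("P2", k=15, delta=3.0, frac_down=0.3)]
        cfg = SimConfig(n_samples=80, n_genes=60, signatures=specs, seed=23)
        ds = simulate_multidataset(cfg, 3, class_skew=[(0.3, 0.3), (0.15, 0.45),
                                                       (0.4, 0.2)])
        datasets = {k: v[0] for k, v in ds.items()}
        truth_sigs = ds["D0"][1].signatures
        rng = np.random.default_rng(2)
        noise = GeneSignature(
            "NOISE",
            up_genes=frozenset(rng.choice(datasets["D0"].gene_ids[30:], 15,
                                          replace=False)),
        )
        sigs = [truth_sigs["P1"], truth_sigs["P2"], noise]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = AipsTrainer(
                datasets, sigs, roi_config=RoiConfig(n_trials=2000, seed=3),
                k_grid=range(1, 9), folds=5, seed=5,
            ).fit()
        assert {m.signature_id for m in results.retained_models} == {"P1", "P2"}

        # held-out validation dataset from the same generative truth
        hold_cfg = SimConfig(n_samples=80, n_genes=60, signatures=specs, seed=24)
        hold_expr, hold_truth = simulate_multidataset(hold_cfg, 1)["D0"]
        from aips.stats import cohen_kappa

        for m in results.retained_models:
            roi_hold = roi_assign(hold_expr, truth_sigs[m.signature_id],
                                  RoiConfig(n_trials=2000, seed=6))
            preds = predict_batch(m, hold_expr)
            res = cohen_kappa(roi_hold.labels.to_numpy(), [p.label for p in preds])
            assert res.kappa > 0 and res.p < 0.01

        text = results.summary()
        assert "retained" in text and "P1" in text
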