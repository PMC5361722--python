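"""Training of absolute single-sample signature models.

The trainer mimics a cohort-level gold standard (region-of-independence
labels computed per dataset) with a classifier that needs only one profile:

1. the ROI partition is computed per training dataset, never on a merged
   matrix (platform heterogeneity rules a merged meta-dataset out);
2. per-sample weights equalize the datasets' total influence;
3. every ordered gene pair (x, y) yields the binary rule
   "expr(x) > expr(y)" whose association with each class is the weighted
   in-class minus out-of-class frequency of the rule being true;
4. the top K rules (interleaved across classes) are combined in a naive
   Bayes classifier; K is chosen by stratified 10-fold cross-validation on
   weighted kappa;
5. models are retained only if their agreement with the gold standard is
   Bonferroni-significant in every training dataset.

Because rules compare two genes within one sample, the resulting models are
invariant to any monotone per-profile transform — the property that makes
them portable across platforms and independent of cohort composition.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSignature, intersect_genes
from .roi import ClassLabel, RoiConfig, SignatureSkipped, roi_assign
from .stats import KappaResult, cohen_kappa
from .winnow import winnow

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSES",
    "GoldStandard",
    "PairRule",
    "AipsModel",
    "RuleMiner",
    "compute_weights",
    "build_gold_standard",
    "score_rules",
    "select_top_k",
    "select_k",
    "fit_naive_bayes",
    "filter_models",
    "train_model",
    "save_models",
    "load_models",
    "AipsTrainer",
    "AipsTrainingResults",
]

#: fixed class order used by every probability table
CLASSES: tuple = (ClassLabel.LOW, ClassLabel.INDEPENDENT, ClassLabel.HIGH)
_CLASS_POS = {c: i for i, c in enumerate(CLASSES)}
#: order in which per-class rule rankings are interleaved into the top-K list
_INTERLEAVE = (ClassLabel.HIGH, ClassLabel.LOW, ClassLabel.INDEPENDENT)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PairRule:
    """Binary predicate ``expr(gene_x) > expr(gene_y)`` tied to one class."""

    gene_x: str
    gene_y: str
    target_class: ClassLabel
    score: float = 0.0

    def __post_init__(self):
        if self.gene_x == self.gene_y:
            raise ValueError("a pair rule needs two distinct genes")


@dataclass
class GoldStandard:
    """Per-(dataset, signature) ROI labels plus dataset-balanced weights.

    ``entries`` has columns sample_id, dataset_id, signature_id, label;
    ``weights`` is indexed by (dataset_id, sample_id) and sums to 1, with
    every dataset contributing the same total.
    """

    entries: pd.DataFrame
    weights: pd.Series

    def labels_for(self, signature_id: str) -> pd.DataFrame:
        return self.entries[self.entries["signature_id"] == signature_id]

    def signature_ids(self) -> list:
        return sorted(self.entries["signature_id"].unique())


def compute_weights(dataset_ids: pd.Series) -> pd.Series:
    """Dataset-balanced per-sample weights: w = 1 / (D * n_d).

    ``dataset_ids`` maps sample id -> dataset id.  Every dataset's weights
    total 1/D, so datasets contribute equally no matter their size; the
    grand total is 1.
    """
    dataset_ids = pd.Series(dataset_ids)
    counts = dataset_ids.value_counts()
    if (counts == 0).any() or len(counts) == 0:
        raise ValueError("every dataset must contain at least one sample")
    d = len(counts)
    w = dataset_ids.map(lambda ds: 1.0 / (d * counts[ds]))
    w.index = pd.MultiIndex.from_arrays(
        [dataset_ids.to_numpy(), dataset_ids.index], names=["dataset_id", "sample_id"]
    )
    w.name = "weight"
    return w


def build_gold_standard(
    datasets: Mapping[str, ExpressionMatrix],
    signatures: Sequence[GeneSignature],
    cfg: RoiConfig | None = None,
) -> GoldStandard:
    """ROI labels per (dataset, signature) — computed per dataset, never merged."""
    cfg = cfg or RoiConfig()
    if not datasets:
        raise ValueError("need at least one training dataset")
    rows = []
    for ds_id, expr in datasets.items():
        for sig in signatures:
            try:
                res = roi_assign(expr, sig, cfg)
            except SignatureSkipped as exc:
                logger.info("gold standard: %s on %s omitted (%s)", sig.signature_id,
                            ds_id, exc)
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": res.labels.index,
                        "dataset_id": ds_id,
                        "signature_id": sig.signature_id,
                        "label": res.labels.to_numpy(),
                    }
                )
            )
    if not rows:
        raise ValueError("no (dataset, signature) pair produced labels")
    entries = pd.concat(rows, ignore_index=True)
    # weights over the union of samples (each sample appears once per dataset)
    per_sample = entries[["sample_id", "dataset_id"]].drop_duplicates()
    sample_ds = pd.Series(
        per_sample["dataset_id"].to_numpy(), index=per_sample["sample_id"].to_numpy()
    )
    weights = compute_weights(sample_ds)
    return GoldStandard(entries=entries, weights=weights)


# ---------------------------------------------------------------------------
# rule mining


class RuleMiner:
    """All ordered gene-pair rule truth values over the training samples.

    Pair p = x * G + y encodes the rule "expr(x) > expr(y)".  The truth
    matrix is cached as float32 (pairs x samples) so that scoring a weight
    vector is a single matrix product; it is shared across signatures and
    CV folds, which all differ only in their weight vectors.
    """

    def __init__(self, expr_by_dataset: Mapping[str, ExpressionMatrix], universe: Sequence[str]):
        self.universe = list(universe)
        g = len(self.universe)
        if g < 2:
            raise ValueError("rule mining needs a universe of at least 2 genes")
        cols = []
        mats = []
        for ds_id, expr in expr_by_dataset.items():
            mats.append(expr.data.loc[self.universe].to_numpy())
            cols.extend((ds_id, s) for s in expr.sample_ids)
        x = np.concatenate(mats, axis=1)
        self.columns = pd.MultiIndex.from_tuples(cols, names=["dataset_id", "sample_id"])
        self.n_samples = x.shape[1]
        self.n_genes = g
        truth = np.empty((g * g, self.n_samples), dtype=np.float32)
        chunk = max(1, (1 << 24) // max(1, g * self.n_samples))
        for start in range(0, g, chunk):
            stop = min(start + chunk, g)
            block = x[start:stop, None, :] > x[None, :, :]
            truth[start * g : stop * g] = block.reshape(-1, self.n_samples)
        self.truth = truth
        self._diag = np.arange(g) * g + np.arange(g)

    def pair_genes(self, pair_id: int) -> tuple[str, str]:
        return self.universe[pair_id // self.n_genes], self.universe[pair_id % self.n_genes]

    def label_weights(self, labels: pd.Series, base_weights: pd.Series) -> np.ndarray:
        """(n_samples, 3) weight matrix: w[s, c] = weight of s if labeled c else 0."""
        w3 = np.zeros((self.n_samples, len(CLASSES)))
        lab = labels.reindex(self.columns)
        wts = base_weights.reindex(self.columns).fillna(0.0).to_numpy()
        for c, j in _CLASS_POS.items():
            mask = (lab == c).to_numpy()
            w3[mask, j] = wts[mask]
        return w3

    def class_scores(self, w3: np.ndarray) -> np.ndarray:
        """score[p, c] = W(rule p true | c) - W(rule p true | not c)."""
        totals = w3.sum(axis=0)
        if (totals <= 0).any():
            missing = [CLASSES[j].value for j in np.where(totals <= 0)[0]]
            raise ValueError(f"no weighted samples for class(es): {missing}")
        grand = totals.sum()
        a = np.empty_like(w3)
        for j in range(w3.shape[1]):
            out = grand - totals[j]
            a[:, j] = w3[:, j] / totals[j] - (w3.sum(axis=1) - w3[:, j]) / out
        scores = self.truth @ a.astype(np.float32)
        scores[self._diag] = -np.inf
        return scores

    def top_pairs(self, scores: np.ndarray, n_top: int) -> dict:
        """Per class, pair ids of the ``n_top`` best scores, descending."""
        out = {}
        n_top = min(n_top, scores.shape[0] - len(self._diag))
        for c, j in _CLASS_POS.items():
            col = scores[:, j]
            idx = np.argpartition(-col, n_top - 1)[:n_top]
            out[c] = idx[np.argsort(-col[idx], kind="stable")]
        return out

    def rule_truth(self, rules: Sequence[PairRule]) -> np.ndarray:
        """(K, n_samples) truth values for explicit rules."""
        gpos = {g: i for i, g in enumerate(self.universe)}
        ids = [gpos[r.gene_x] * self.n_genes + gpos[r.gene_y] for r in rules]
        return self.truth[ids]


def score_rules(
    expr_by_dataset: Mapping[str, ExpressionMatrix],
    gold: GoldStandard,
    signature_id: str,
    universe: Sequence[str],
    n_top: int = 1000,
    miner: RuleMiner | None = None,
) -> dict:
    """Ranked pair rules per class for one signature.

    Returns ``{class: [PairRule, ...]}`` with rules sorted by association
    score (weighted in-class minus out-of-class frequency of the rule being
    true) in descending order; both orientations of every gene pair are
    scored because (x, y) and (y, x) are distinct ordered pairs.
    """
    miner = miner or RuleMiner(expr_by_dataset, universe)
    labels = _signature_labels(gold, signature_id)
    w3 = miner.label_weights(labels, gold.weights)
    scores = miner.class_scores(w3)
    ranked = miner.top_pairs(scores, n_top)
    out = {}
    for c, ids in ranked.items():
        j = _CLASS_POS[c]
        out[c] = [
            PairRule(*miner.pair_genes(int(p)), target_class=c, score=float(scores[p, j]))
            for p in ids
        ]
    return out


def _signature_labels(gold: GoldStandard, signature_id: str) -> pd.Series:
    sub = gold.labels_for(signature_id)
    if sub.empty:
        raise ValueError(f"gold standard has no entries for {signature_id!r}")
    idx = pd.MultiIndex.from_arrays(
        [sub["dataset_id"], sub["sample_id"]], names=["dataset_id", "sample_id"]
    )
    return pd.Series(sub["label"].to_numpy(), index=idx)


def select_top_k(ranked: Mapping[ClassLabel, Sequence[PairRule]], k: int) -> list:
    """Interleave the per-class rankings (high, low, independent) into K rules.

    Deduplicates on the (gene_x, gene_y) pair so one orientation serves one
    class; interleaving guarantees no class's rule list is starved.
    """
    iters = {c: iter(ranked.get(c, ())) for c in _INTERLEAVE}
    seen: set = set()
    out: list = []
    exhausted: set = set()
    while len(out) < k and len(exhausted) < len(iters):
        for c in _INTERLEAVE:
            if len(out) >= k or c in exhausted:
                continue
            for rule in iters[c]:
                key = (rule.gene_x, rule.gene_y)
                if key not in seen:
                    seen.add(key)
                    out.append(rule)
                    break
            else:
                exhausted.add(c)
    return out


# ---------------------------------------------------------------------------
# naive Bayes


@dataclass(eq=False)
class AipsModel:
    """A trained absolute classifier for one signature.

    ``cond_prob[r, c]`` is P(rule r true | class c) with Laplace smoothing on
    effective (weight-rescaled) counts; ``priors`` are the weighted class
    frequencies.  Prediction needs nothing but this object and one profile.
    """

    signature_id: str
    rules: list
    cond_prob: np.ndarray  # (K, 3), class order CLASSES
    priors: np.ndarray  # (3,)
    k: int
    training_meta: dict = field(default_factory=dict)
    retained: bool | None = None
    kappa_by_dataset: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cond_prob = np.asarray(self.cond_prob, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if self.cond_prob.shape != (len(self.rules), len(CLASSES)):
            raise ValueError("cond_prob must be (K, 3)")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        if ((self.cond_prob <= 0) | (self.cond_prob >= 1)).any():
            raise ValueError("cond_prob must lie strictly in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "signature_id": self.signature_id,
            "K": self.k,
            "rules": [
                {"x": r.gene_x, "y": r.gene_y, "target_class": r.target_class.value,
                 "score": r.score}
                for r in self.rules
            ],
            "cond_prob": self.cond_prob.tolist(),
            "priors": self.priors.tolist(),
            "class_order": [c.value for c in CLASSES],
            "meta": _jsonable(self.training_meta),
            "retained": self.retained,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AipsModel":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema: {d.get('schema_version')}")
        rules = [
            PairRule(r["x"], r["y"], ClassLabel(r["target_class"]), r.get("score", 0.0))
            for r in d["rules"]
        ]
        return cls(
            signature_id=d["signature_id"],
            rules=rules,
            cond_prob=np.asarray(d["cond_prob"]),
            priors=np.asarray(d["priors"]),
            k=d["K"],
            training_meta=d.get("meta", {}),
            retained=d.get("retained"),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, ClassLabel):
        return obj.value
    return obj


def save_models(models: Sequence[AipsModel], path) -> None:
    with open(path, "w") as fh:
        json.dump({"schema_version": SCHEMA_VERSION,
                   "models": [m.to_dict() for m in models]}, fh, indent=1)


def load_models(path) -> list:
    with open(path) as fh:
        payload = json.load(fh)
    return [AipsModel.from_dict(d) for d in payload["models"]]


def _fit_nb_arrays(
    truth: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    alpha: float = 1.0,
    uniform_priors: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed conditional tables and priors from (K, n) truth values.

    Weights are rescaled so they sum to the number of labeled samples
    ("effective n"); Laplace alpha then acts on count scale:
    P(true | c) = (eff_true_c + alpha) / (eff_c + 2 alpha).
    """
    n = truth.shape[1]
    w = weights * (n / weights.sum())
    cond = np.empty((truth.shape[0], len(CLASSES)))
    priors = np.empty(len(CLASSES))
    for c, j in _CLASS_POS.items():
        mask = labels == c
        wc = w[mask]
        if wc.sum() <= 0:
            raise ValueError(f"gold standard contains no {c.value!r} samples")
        eff_true = truth[:, mask] @ wc
        cond[:, j] = (eff_true + alpha) / (wc.sum() + 2 * alpha)
        priors[j] = wc.sum()
    priors = np.full(len(CLASSES), 1 / len(CLASSES)) if uniform_priors else priors / priors.sum()
    return cond, priors


def _nb_predict_arrays(
    truth: np.ndarray, cond: np.ndarray, priors: np.ndarray
) -> tuple[np.ndarray, list]:
    """Posterior matrix (n, 3) and argmax labels (ties -> independent)."""
    log_p = np.log(cond)
    log_q = np.log1p(-cond)
    ll = truth.T @ log_p + (1.0 - truth.T) @ log_q + np.log(priors)
    ll -= ll.max(axis=1, keepdims=True)
    post = np.exp(ll)
    post /= post.sum(axis=1, keepdims=True)
    labels = []
    for row in post:
        top = row.max()
        winners = np.where(np.isclose(row, top, rtol=0, atol=1e-12))[0]
        labels.append(CLASSES[winners[0]] if len(winners) == 1 else ClassLabel.INDEPENDENT)
    return post, labels


def fit_naive_bayes(
    rules: Sequence[PairRule],
    expr_by_dataset: Mapping[str, ExpressionMatrix],
    gold: GoldStandard,
    signature_id: str,
    alpha: float = 1.0,
    uniform_priors: bool = False,
    training_meta: dict | None = None,
) -> AipsModel:
    """Fit the naive Bayes combination of the given rules on the gold standard."""
    if not rules:
        raise ValueError("need at least one rule")
    labels = _signature_labels(gold, signature_id)
    truth_cols, lab_arr, w_arr = _aligned_truth(rules, expr_by_dataset, labels, gold.weights)
    cond, priors = _fit_nb_arrays(truth_cols, lab_arr, w_arr, alpha, uniform_priors)
    return AipsModel(
        signature_id=signature_id,
        rules=list(rules),
        cond_prob=cond,
        priors=priors,
        k=len(rules),
        training_meta=training_meta or {},
    )


def _aligned_truth(rules, expr_by_dataset, labels: pd.Series, weights: pd.Series):
    """Rule truth values, labels and weights aligned over labeled samples."""
    truth_blocks, lab_blocks, w_blocks = [], [], []
    for ds_id, expr in expr_by_dataset.items():
        if ds_id not in labels.index.get_level_values(0):
            continue
        ds_labels = labels.loc[ds_id]
        cols = [s for s in expr.sample_ids if s in ds_labels.index]
        if not cols:
            continue
        x = expr.data[cols]
        t = np.stack([(x.loc[r.gene_x] > x.loc[r.gene_y]).to_numpy() for r in rules])
        truth_blocks.append(t.astype(float))
        lab_blocks.append(ds_labels.loc[cols].to_numpy())
        w_blocks.append(weights.loc[ds_id].loc[cols].to_numpy())
    if not truth_blocks:
        raise ValueError("no labeled samples found in the training datasets")
    return (
        np.concatenate(truth_blocks, axis=1),
        np.concatenate(lab_blocks),
        np.concatenate(w_blocks),
    )


# ---------------------------------------------------------------------------
# K selection by cross-validation


def _stratified_folds(
    strat_keys: Sequence, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold id per sample, dealing each stratum round-robin after a shuffle."""
    strat_keys = np.asarray([str(k) for k in strat_keys], dtype=object)
    folds = np.zeros(len(strat_keys), dtype=int)
    for key in np.unique(strat_keys):
        idx = np.where(strat_keys == key)[0]
        rng.shuffle(idx)
        folds[idx] = (np.arange(len(idx)) + rng.integers(n_folds)) % n_folds
    return folds


def select_k(
    expr_by_dataset: Mapping[str, ExpressionMatrix],
    gold: GoldStandard,
    signature_id: str,
    universe: Sequence[str],
    k_grid: Sequence[int] = tuple(range(1, 51)),
    folds: int = 10,
    seed: int = 0,
    miner: RuleMiner | None = None,
    alpha: float = 1.0,
) -> tuple[int, dict]:
    """Choose the rule count K by stratified cross-validated weighted kappa.

    Folds are stratified jointly by class and dataset; within each fold the
    rules are re-ranked on the training part only.  Returns (K, cv_table)
    where cv_table maps each K to its mean held-out kappa; ties go to the
    smallest K.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k_grid is empty")
    miner = miner or RuleMiner(expr_by_dataset, universe)
    labels = _signature_labels(gold, signature_id)
    lab_full = labels.reindex(miner.columns)
    labeled = lab_full.notna().to_numpy()
    lab_arr = lab_full.to_numpy()
    w_full = gold.weights.reindex(miner.columns).fillna(0.0).to_numpy()
    w_full = np.where(labeled, w_full, 0.0)

    class_counts = pd.Series(lab_arr[labeled]).value_counts()
    n_folds = folds
    if class_counts.min() < folds:
        n_folds = max(2, int(class_counts.min()))
        warnings.warn(
            f"{signature_id}: smallest class has {int(class_counts.min())} samples; "
            f"reducing CV folds to {n_folds}"
        )

    rng = np.random.default_rng(seed)
    strat = [
        f"{miner.columns[i][0]}|{getattr(lab_arr[i], 'value', lab_arr[i])}"
        for i in np.where(labeled)[0]
    ]
    fold_of_labeled = _stratified_folds(strat, n_folds, rng)
    fold_ids = np.full(miner.n_samples, -1, dtype=int)
    fold_ids[np.where(labeled)[0]] = fold_of_labeled

    max_k = max(k_grid)
    kappas = {k: [] for k in k_grid}
    for f in range(n_folds):
        train_mask = labeled & (fold_ids != f)
        test_mask = labeled & (fold_ids == f)
        if not test_mask.any() or not train_mask.any():
            continue
        w3 = np.zeros((miner.n_samples, len(CLASSES)))
        for c, j in _CLASS_POS.items():
            sel = train_mask & (lab_arr == c)
            w3[sel, j] = w_full[sel]
        try:
            scores = miner.class_scores(w3)
        except ValueError:  # a fold lost an entire class despite stratification
            continue
        # generous pool so interleaving+dedup can still fill max_k rules
        ranked = miner.top_pairs(scores, min(3 * max_k + 3, miner.truth.shape[0]))
        rule_pool = {
            c: [
                PairRule(*miner.pair_genes(int(p)), target_class=c,
                         score=float(scores[p, _CLASS_POS[c]]))
                for p in ids
            ]
            for c, ids in ranked.items()
        }
        top_rules = select_top_k(rule_pool, max_k)
        truth_all = miner.rule_truth(top_rules)
        for k in k_grid:
            t_train = truth_all[:k][:, train_mask]
            cond, priors = _fit_nb_arrays(
                t_train, lab_arr[train_mask], w_full[train_mask], alpha
            )
            _, pred = _nb_predict_arrays(truth_all[:k][:, test_mask], cond, priors)
            res = cohen_kappa(
                lab_arr[test_mask], pred, sample_weight=w_full[test_mask]
            )
            kappas[k].append(0.0 if res.degenerate or np.isnan(res.kappa) else res.kappa)

    cv_table = {k: (float(np.mean(v)) if v else float("-inf")) for k, v in kappas.items()}
    best = max(cv_table.values())
    k_best = min(k for k, v in cv_table.items() if v >= best - 1e-12)
    return k_best, cv_table


def train_model(
    expr_by_dataset: Mapping[str, ExpressionMatrix],
    gold: GoldStandard,
    signature_id: str,
    universe: Sequence[str],
    k_grid: Sequence[int] = tuple(range(1, 51)),
    folds: int = 10,
    seed: int = 0,
    miner: RuleMiner | None = None,
    alpha: float = 1.0,
    uniform_priors: bool = False,
) -> AipsModel:
    """Full single-signature pipeline: CV-select K, rank rules on all data, fit NB."""
    miner = miner or RuleMiner(expr_by_dataset, universe)
    k_best, cv_table = select_k(
        expr_by_dataset, gold, signature_id, universe,
        k_grid=k_grid, folds=folds, seed=seed, miner=miner, alpha=alpha,
    )
    ranked = score_rules(
        expr_by_dataset, gold, signature_id, universe,
        n_top=3 * k_best + 3, miner=miner,
    )
    rules = select_top_k(ranked, k_best)
    meta = {
        "datasets": list(expr_by_dataset.keys()),
        "seed": seed,
        "cv_table": {str(k): v for k, v in cv_table.items()},
        "universe_size": len(universe),
    }
    return fit_naive_bayes(
        rules, expr_by_dataset, gold, signature_id,
        alpha=alpha, uniform_priors=uniform_priors, training_meta=meta,
    )


def filter_models(
    models: Sequence[AipsModel],
    expr_by_dataset: Mapping[str, ExpressionMatrix],
    gold: GoldStandard,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> list:
    """Keep models whose kappa against the gold standard is Bonferroni-significant
    in every training dataset; sets ``retained`` and ``kappa_by_dataset`` on each.

    The Bonferroni family defaults to the number of candidate models (one
    kappa test per model per dataset, corrected across models).
    """
    from .predict import predict_batch  # local import: predict depends on this module

    n_tests = n_tests if n_tests is not None else len(models)
    retained = []
    for model in models:
        labels = _signature_labels(gold, model.signature_id)
        ok = True
        model.kappa_by_dataset = {}
        for ds_id, expr in expr_by_dataset.items():
            if ds_id not in labels.index.get_level_values(0):
                ok = False
                break
            ds_labels = labels.loc[ds_id]
            preds = predict_batch(model, expr.subset_samples(list(ds_labels.index)))
            res = cohen_kappa(ds_labels.to_numpy(), [p.label for p in preds])
            model.kappa_by_dataset[ds_id] = res
            if res.degenerate or np.isnan(res.p) or res.p * n_tests >= alpha:
                ok = False
        model.retained = ok
        if ok:
            retained.append(model)
    return retained


# ---------------------------------------------------------------------------
# statsmodels-style driver


@dataclass
class AipsTrainingResults:
    """Everything `AipsTrainer.fit` produced: gold standard, winnow reports,
    all candidate models and the retained subset."""

    models: list
    retained_models: list
    gold: GoldStandard
    winnow_reports: list
    universe: list
    alpha: float

    def model_for(self, signature_id: str) -> AipsModel:
        for m in self.models:
            if m.signature_id == signature_id:
                return m
        raise KeyError(signature_id)

    def save(self, path, retained_only: bool = True) -> None:
        save_models(self.retained_models if retained_only else self.models, path)

    def summary(self) -> str:
        lines = [
            "Absolute signature model training",
            f"  gene universe: {len(self.universe)} genes",
            f"  candidate signatures: {len(self.winnow_reports)}"
            f"  informative: {sum(r.informative for r in self.winnow_reports)}",
            f"  trained models: {len(self.models)}"
            f"  retained (Bonferroni alpha={self.alpha}): {len(self.retained_models)}",
            "",
            f"  {'signature':<24} {'K':>4} {'min kappa':>10} {'max p':>10} retained",
        ]
        for m in self.models:
            if m.kappa_by_dataset:
                min_k = min(r.kappa for r in m.kappa_by_dataset.values())
                max_p = max(r.p for r in m.kappa_by_dataset.values())
                lines.append(
                    f"  {m.signature_id:<24} {m.k:>4} {min_k:>10.3f} {max_p:>10.2e} "
                    f"{bool(m.retained)}"
                )
            else:
                lines.append(f"  {m.signature_id:<24} {m.k:>4} {'-':>10} {'-':>10} "
                             f"{bool(m.retained)}")
        return "\n".join(lines)


class AipsTrainer:
    """Model-style facade over the full training pipeline.

    Winnows the signature compendium on the largest training dataset,
    computes the per-dataset gold standard, mines pair rules, selects K by
    cross-validation, fits the naive Bayes models and applies the
    per-dataset kappa retention filter.

    Example
    -------
    >>> trainer = AipsTrainer(datasets, signatures, k_grid=range(1, 26), seed=7)
    >>> results = trainer.fit()
    >>> print(results.summary())
    """

    def __init__(
        self,
        datasets: Mapping[str, ExpressionMatrix],
        signatures: Sequence[GeneSignature],
        roi_config: RoiConfig | None = None,
        k_grid: Sequence[int] = tuple(range(1, 51)),
        folds: int = 10,
        alpha: float = 0.05,
        winnow_cutoff: float = 0.8,
        do_winnow: bool = True,
        nb_alpha: float = 1.0,
        uniform_priors: bool = False,
        seed: int = 0,
    ):
        if not datasets:
            raise ValueError("need at least one training dataset")
        self.datasets = dict(datasets)
        self.signatures = list(signatures)
        self.roi_config = roi_config or RoiConfig(seed=seed)
        self.k_grid = list(k_grid)
        self.folds = folds
        self.alpha = alpha
        self.winnow_cutoff = winnow_cutoff
        self.do_winnow = do_winnow
        self.nb_alpha = nb_alpha
        self.uniform_priors = uniform_priors
        self.seed = seed

    def fit(self) -> AipsTrainingResults:
        harmonized = intersect_genes(list(self.datasets.values()))
        datasets = dict(zip(self.datasets.keys(), harmonized))
        universe = harmonized[0].gene_ids

        if self.do_winnow:
            largest = max(datasets, key=lambda d: datasets[d].n_samples)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reports = winnow(
                    datasets[largest], self.signatures, self.roi_config,
                    cutoff=self.winnow_cutoff,
                )
            informative = {r.signature_id for r in reports if r.informative}
            signatures = [s for s in self.signatures if s.signature_id in informative]
        else:
            reports = []
            signatures = self.signatures
        if not signatures:
            raise ValueError("no informative signatures survive winnowing")

        gold = build_gold_standard(datasets, signatures, self.roi_config)
        miner = RuleMiner(datasets, universe)
        models = []
        for sig in signatures:
            if sig.signature_id not in gold.entries["signature_id"].values:
                continue
            models.append(
                train_model(
                    datasets, gold, sig.signature_id, universe,
                    k_grid=self.k_grid, folds=self.folds, seed=self.seed,
                    miner=miner, alpha=self.nb_alpha,
                    uniform_priors=self.uniform_priors,
                )
            )
        retained = filter_models(models, datasets, gold, alpha=self.alpha)
        return AipsTrainingResults(
            models=models,
            retained_models=retained,
            gold=gold,
            winnow_reports=reports,
            universe=universe,
            alpha=self.alpha,
        )
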