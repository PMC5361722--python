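"""Cohort-composition instability experiment.

Relative pathway scorers standardize each gene against the cohort at hand,
so a sample's score moves when the cohort around it changes — e.g. when the
dataset is restricted to one receptor-status stratum.  This module scores
every sample twice (full cohort vs its stratum only) and reports the
absolute shift; an absolute classifier's posteriors cannot shift at all.

Only the z-score combiner is implemented natively (it is one formula);
any other scorer can be plugged in as a callable ``scorer(expr, sig) ->
per-sample Series``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSignature
from .roi import ClassLabel

__all__ = ["ScoreShift", "zscore_signature", "aips_scorer", "stability_experiment"]


@dataclass
class ScoreShift:
    sample_id: str
    signature_id: str
    score_all: float
    score_stratum: float

    @property
    def abs_diff(self) -> float:
        return abs(self.score_all - self.score_stratum)


def zscore_signature(
    expr: ExpressionMatrix,
    sig: GeneSignature,
    population_sd: bool = True,
) -> pd.Series:
    """Combined z score per sample: sum_g z_g / sqrt(k).

    Each signature gene is standardized across the cohort (population sd by
    default, for determinism); down-directed genes are negated after
    standardization.  Zero-variance genes are dropped with a warning.
    """
    genes = sorted(sig.genes & set(expr.gene_ids))
    if not genes:
        raise ValueError(f"no genes of {sig.signature_id!r} present in the matrix")
    x = expr.data.loc[genes].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0 if population_sd else 1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        warnings.warn(
            f"{sig.signature_id}: dropping {int((~keep).sum())} zero-variance genes"
        )
    if not keep.any():
        warnings.warn(f"{sig.signature_id}: all genes zero-variance; scores set to 0")
        return pd.Series(0.0, index=expr.sample_ids, name=sig.signature_id)
    z = (x[keep] - mu[keep]) / sd[keep]
    signs = np.array([-1.0 if g in sig.down_genes else 1.0 for g in genes])[keep]
    combined = (signs[:, None] * z).sum(axis=0) / np.sqrt(keep.sum())
    return pd.Series(combined, index=expr.sample_ids, name=sig.signature_id)


def aips_scorer(models: Mapping[str, "AipsModel"]) -> Callable:
    """Adapter turning trained absolute models into a scorer for the experiment.

    The score is the posterior probability of the ``high`` class — a pure
    function of (model, profile), so its full-cohort and stratum-restricted
    values coincide exactly.
    """
    from .predict import predict_batch

    def scorer(expr: ExpressionMatrix, sig: GeneSignature) -> pd.Series:
        model = models[sig.signature_id]
        preds = predict_batch(model, expr)
        return pd.Series(
            [p.posteriors[ClassLabel.HIGH] for p in preds],
            index=expr.sample_ids,
            name=sig.signature_id,
        )

    return scorer


def stability_experiment(
    expr: ExpressionMatrix,
    signatures: Sequence[GeneSignature],
    strata: pd.Series,
    scorer: str | Callable = "zscore",
    models: Mapping[str, "AipsModel"] | None = None,
) -> list:
    """Score each sample in the full cohort and in its stratum-only cohort.

    ``strata`` maps sample id -> stratum label and must partition the
    samples.  ``scorer`` is ``"zscore"``, ``"aips"`` (requires ``models``),
    or any callable ``(expr, sig) -> Series``.
    """
    strata = pd.Series(strata)
    missing = set(expr.sample_ids) - set(strata.index)
    if missing:
        raise ValueError(f"strata missing for {len(missing)} samples")
    if callable(scorer):
        score_fn = scorer
    elif scorer == "zscore":
        score_fn = zscore_signature
    elif scorer == "aips":
        if models is None:
            raise ValueError("scorer='aips' requires trained models")
        score_fn = aips_scorer(models)
    else:
        raise ValueError(f"unknown scorer {scorer!r}")

    sub_cohorts = {}
    for stratum in strata.unique():
        samples = [s for s in expr.sample_ids if strata[s] == stratum]
        if len(samples) < 10:
            warnings.warn(
                f"stratum {stratum!r} has only {len(samples)} samples; "
                "relative standardization is unstable"
            )
        sub_cohorts[stratum] = expr.subset_samples(samples)

    shifts = []
    for sig in signatures:
        full = score_fn(expr, sig)
        for stratum, sub in sub_cohorts.items():
            part = score_fn(sub, sig)
            for s in sub.sample_ids:
                shifts.append(
                    ScoreShift(
                        sample_id=s,
                        signature_id=sig.signature_id,
                        score_all=float(full[s]),
                        score_stratum=float(part[s]),
                    )
                )
    return shifts


def shifts_frame(shifts: Sequence[ScoreShift]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in shifts],
            "signature_id": [s.signature_id for s in shifts],
            "score_all": [s.score_all for s in shifts],
            "score_stratum": [s.score_stratum for s in shifts],
            "abs_diff": [s.abs_diff for s in shifts],
        }
    )
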