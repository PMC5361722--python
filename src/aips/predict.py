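"""Apply a trained absolute model to expression profiles.

A prediction is a pure function of (model, one profile): each gene-pair
rule is evaluated as a strict within-sample comparison, the naive Bayes
posterior is computed in log space, and the argmax class is returned.  No
other sample is consulted, so calls cannot shift when the surrounding
cohort changes, and any strictly increasing transform of the whole profile
leaves every rule — hence the call — untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .roi import ClassLabel
from .train import CLASSES, AipsModel

__all__ = ["Prediction", "CoverageError", "predict_single", "predict_batch"]


class CoverageError(ValueError):
    """Too many rule genes are missing from the profile to trust a call."""


@dataclass
class Prediction:
    sample_id: str
    signature_id: str
    label: ClassLabel
    posteriors: dict
    rules_evaluated: int
    rules_missing: int

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "signature_id": self.signature_id,
            "label": self.label.value,
            "p_low": self.posteriors[ClassLabel.LOW],
            "p_ind": self.posteriors[ClassLabel.INDEPENDENT],
            "p_high": self.posteriors[ClassLabel.HIGH],
            "rules_missing": self.rules_missing,
        }


def predict_single(
    model: AipsModel,
    profile: pd.Series | Mapping[str, float],
    sample_id: str = "sample",
    missing_threshold: float = 0.5,
) -> Prediction:
    """Classify one expression profile with one model.

    Rules whose genes are absent from the profile are dropped (and counted);
    the likelihood is renormalized over the evaluated rules.  If more than
    ``missing_threshold`` of the rules are missing the call is refused with
    :class:`CoverageError`.  Equal expression makes a rule false (strict
    ``>``), and an exact posterior tie yields ``independent``.
    """
    if not isinstance(profile, pd.Series):
        profile = pd.Series(profile)
    obs, keep = [], []
    for i, rule in enumerate(model.rules):
        if rule.gene_x in profile.index and rule.gene_y in profile.index:
            keep.append(i)
            obs.append(float(profile[rule.gene_x]) > float(profile[rule.gene_y]))
    n_missing = len(model.rules) - len(keep)
    if n_missing > missing_threshold * len(model.rules):
        raise CoverageError(
            f"{model.signature_id}: {n_missing}/{len(model.rules)} rules have "
            f"missing genes (threshold {missing_threshold:.0%})"
        )

    cond = model.cond_prob[keep]
    obs_arr = np.asarray(obs, dtype=float)
    log_lik = (
        obs_arr @ np.log(cond) + (1.0 - obs_arr) @ np.log1p(-cond) + np.log(model.priors)
    )
    log_lik -= log_lik.max()
    post = np.exp(log_lik)
    post /= post.sum()

    top = post.max()
    winners = np.where(np.isclose(post, top, rtol=0, atol=1e-12))[0]
    label = CLASSES[winners[0]] if len(winners) == 1 else ClassLabel.INDEPENDENT
    return Prediction(
        sample_id=sample_id,
        signature_id=model.signature_id,
        label=label,
        posteriors={c: float(post[j]) for j, c in enumerate(CLASSES)},
        rules_evaluated=len(keep),
        rules_missing=n_missing,
    )


def predict_batch(
    model: AipsModel,
    expr: ExpressionMatrix,
    missing_threshold: float = 0.5,
) -> list:
    """Column-wise :func:`predict_single`; each sample's result is identical to
    predicting it alone (the absoluteness contract)."""
    return [
        predict_single(model, expr.profile(s), sample_id=s,
                       missing_threshold=missing_threshold)
        for s in expr.sample_ids
    ]


def predictions_frame(predictions) -> pd.DataFrame:
    return pd.DataFrame([p.to_row() for p in predictions])
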