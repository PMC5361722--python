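"""Winnowing: keep only signatures whose cohort partition beats random.

A signature whose region of independence swallows more than ``cutoff``
(default 0.8) of the cohort partitions no better than a random gene set and
is dropped before model training.  The permuted control — the same matrix
with gene labels shuffled once — estimates how an uninformative signature
behaves on this cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSignature
from .roi import ClassLabel, RoiConfig, SignatureSkipped, roi_assign

__all__ = ["WinnowReport", "permute_gene_labels", "winnow"]

SMALL_COHORT_WARNING = 200


@dataclass
class WinnowReport:
    signature_id: str
    frac_low: float
    frac_independent: float
    frac_high: float
    frac_independent_permuted: float
    informative: bool
    reason: str | None = None  # e.g. "too_few_genes" for skipped signatures


def permute_gene_labels(expr: ExpressionMatrix, seed: int = 0) -> ExpressionMatrix:
    """Shuffle which gene id names which row; row vectors are untouched."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(expr.n_genes)
    data = expr.data.copy()
    data.index = pd.Index(np.asarray(expr.gene_ids, dtype=object)[perm], name=data.index.name)
    return ExpressionMatrix(data, annotations=expr.annotations)


def winnow(
    expr: ExpressionMatrix,
    signatures: Sequence[GeneSignature],
    cfg: RoiConfig | None = None,
    cutoff: float = 0.8,
    permuted_expr: ExpressionMatrix | None = None,
) -> list:
    """Score every signature's partition against the independence cutoff.

    ``informative`` is True iff the fraction of samples inside the region of
    independence does not exceed ``cutoff``.  The gene-label-permuted
    control is computed once per dataset (pass ``permuted_expr`` to reuse
    one across calls) and shared by all signatures.
    """
    cfg = cfg or RoiConfig()
    if expr.n_samples < SMALL_COHORT_WARNING:
        warnings.warn(
            f"winnowing on only {expr.n_samples} samples; the region of "
            f"independence is unstable below {SMALL_COHORT_WARNING}"
        )
    if permuted_expr is None:
        permuted_expr = permute_gene_labels(expr, seed=cfg.seed)

    reports = []
    for sig in signatures:
        try:
            res = roi_assign(expr, sig, cfg)
        except SignatureSkipped:
            reports.append(
                WinnowReport(sig.signature_id, np.nan, np.nan, np.nan, np.nan,
                             informative=False, reason="too_few_genes")
            )
            continue
        fr = res.label_fractions()
        try:
            frac_ind_perm = roi_assign(permuted_expr, sig, cfg).label_fractions()[
                ClassLabel.INDEPENDENT
            ]
        except SignatureSkipped:
            frac_ind_perm = np.nan
        reports.append(
            WinnowReport(
                signature_id=sig.signature_id,
                frac_low=fr[ClassLabel.LOW],
                frac_independent=fr[ClassLabel.INDEPENDENT],
                frac_high=fr[ClassLabel.HIGH],
                frac_independent_permuted=frac_ind_perm,
                informative=bool(fr[ClassLabel.INDEPENDENT] <= cutoff),
            )
        )
    return reports
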