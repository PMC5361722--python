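"""Agreement and association statistics: Cohen's kappa with a large-sample
significance test, Fisher's exact association, Benjamini-Hochberg FDR, and a
thin Kruskal-Wallis wrapper."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KappaResult",
    "cohen_kappa",
    "fisher_association",
    "bh_fdr",
    "kruskal_wallis",
]


@dataclass
class KappaResult:
    """Cohen's kappa with the classical large-sample null z test.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and p_e
    the chance agreement from the raters' marginals.  Under the null of
    independent raters with the observed marginals,

        var0(kappa) = [p_e + p_e^2 - sum_c a_c * b_c * (a_c + b_c)]
                      / [n * (1 - p_e)^2]

    (a_c, b_c the two marginal frequencies of class c), z = kappa / se0 and
    the two-sided p comes from the normal approximation.
    """

    kappa: float
    p_o: float
    p_e: float
    se0: float
    z: float
    p: float
    n: int
    degenerate: bool = False


def _as_labels(v) -> np.ndarray:
    return np.asarray([getattr(x, "value", x) for x in v], dtype=object)


def cohen_kappa(labels_a, labels_b, sample_weight=None) -> KappaResult:
    """Chance-corrected agreement between two paired categorical vectors.

    ``sample_weight`` (optional, positive) weights both the agreement and
    the marginals; the z test then uses the effective sample size
    (sum w)^2 / sum w^2.
    """
    a = _as_labels(labels_a)
    b = _as_labels(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labels_a and labels_b must be equal-length 1-d vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 paired labels")
    if sample_weight is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weight, dtype=float)
        if w.shape != a.shape or (w <= 0).any():
            raise ValueError("sample_weight must be positive and match labels")
    w = w / w.sum()
    n_eff = int(round(1.0 / np.square(w).sum()))

    classes = sorted(set(a) | set(b))
    p_o = float(np.sum(w * (a == b)))
    marg_a = np.array([np.sum(w * (a == c)) for c in classes])
    marg_b = np.array([np.sum(w * (b == c)) for c in classes])
    p_e = float(marg_a @ marg_b)

    if p_e >= 1.0 - 1e-12:
        warnings.warn("both raters constant and equal: kappa undefined")
        return KappaResult(np.nan, p_o, p_e, np.nan, np.nan, np.nan, n, degenerate=True)

    kappa = (p_o - p_e) / (1.0 - p_e)
    var0 = (p_e + p_e**2 - float(np.sum(marg_a * marg_b * (marg_a + marg_b)))) / (
        n_eff * (1.0 - p_e) ** 2
    )
    se0 = float(np.sqrt(max(var0, 0.0)))
    if se0 == 0.0:
        z = np.inf if kappa > 0 else (-np.inf if kappa < 0 else 0.0)
    else:
        z = kappa / se0
    p = float(2.0 * sps.norm.sf(abs(z)))
    return KappaResult(float(kappa), p_o, p_e, se0, float(z), p, n)


def fisher_association(
    labels,
    groups,
    n_mc: int = 10_000,
    seed: int = 0,
    force_chi2: bool = False,
) -> float:
    """Two-sided p-value for association between two categorical vectors.

    2x2 tables use the exact hypergeometric test; larger tables use a seeded
    Monte-Carlo permutation of the labels with the chi-square statistic
    (``force_chi2=True`` skips the permutation and returns the asymptotic
    chi-square p instead).  Degenerate tables (a single distinct label or
    group) return p = 1 with a warning.
    """
    lab = _as_labels(labels)
    grp = _as_labels(groups)
    if lab.shape != grp.shape:
        raise ValueError("labels and groups must have equal length")
    table = pd.crosstab(pd.Series(lab), pd.Series(grp)).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        warnings.warn("degenerate contingency table (single row or column); p = 1")
        return 1.0
    if table.shape == (2, 2):
        return float(sps.fisher_exact(table, alternative="two-sided")[1])
    if force_chi2:
        return float(sps.chi2_contingency(table)[1])

    obs = _chi2_stat(table)
    rng = np.random.default_rng(seed)
    hits = 0
    lab_work = lab.copy()
    codes_g = pd.factorize(grp)[0]
    codes_l = pd.factorize(lab_work)[0]
    n_l, n_g = codes_l.max() + 1, codes_g.max() + 1
    for _ in range(n_mc):
        rng.shuffle(codes_l)
        perm_table = np.bincount(
            codes_l * n_g + codes_g, minlength=n_l * n_g
        ).reshape(n_l, n_g)
        if _chi2_stat(perm_table) >= obs - 1e-12:
            hits += 1
    return float((hits + 1) / (n_mc + 1))


def _chi2_stat(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H and p for ``values`` split by ``groups``."""
    v = np.asarray(values, dtype=float)
    g = _as_labels(groups)
    samples = [v[g == c] for c in sorted(set(g))]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    stat, p = sps.kruskal(*samples)
    return float(stat), float(p)
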