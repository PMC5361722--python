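"""Region-of-independence (ROI_q) partitioning of a cohort for one signature.

The procedure ranks samples per signature gene (down-directed genes are
negated first, so low expression earns a high rank), sums the ranks over the
k genes present, and linearly orders samples by that rank sum.  The null is
an "artificial patient": each of the k genes assigns it an integer rank
drawn uniformly from {0, ..., n+1}, and the k draws are summed.  The ROI at
quantile q is the rank-sum interval containing q of the null trials
(symmetric nearest-rank empirical quantiles); samples below it are called
``low``, above it ``high``, inside it ``independent``.

Because everything is rank-based, the partition is invariant under any
strictly increasing per-gene transform of the expression values.  The
partition is a cohort-level construct: adding a sample can move the ranks,
and hence the labels, of other samples (the absolute models in
:mod:`aips.train` / :mod:`aips.predict` exist precisely to remove that
dependence).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSignature

__all__ = [
    "ClassLabel",
    "RoiConfig",
    "RoiResult",
    "SignatureSkipped",
    "SignatureROI",
    "directed_ranks",
    "rank_sum_order",
    "null_rank_sums",
    "exact_null_pmf",
    "exact_null_region",
    "compute_region",
    "roi_assign",
]


class ClassLabel(str, Enum):
    """Three-state activation call for a signature in a sample."""

    LOW = "low"
    INDEPENDENT = "independent"
    HIGH = "high"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SignatureSkipped(ValueError):
    """Too few signature genes present in the matrix; carries the count."""

    def __init__(self, signature_id: str, n_present: int, required: int):
        super().__init__(
            f"signature {signature_id!r}: only {n_present} genes present "
            f"(minimum {required})"
        )
        self.signature_id = signature_id
        self.n_present = n_present
        self.required = required


@dataclass
class RoiConfig:
    """Tuning knobs of the ROI_q procedure.

    q : central null coverage defining the region of independence.
    n_trials : number of artificial-patient permutation trials.
    seed : base seed; each signature gets its own derived RNG stream so
        batch results do not depend on processing order.
    min_genes_present : signatures with fewer matrix genes are skipped.
    integer_null : draw integer ranks from {0..n+1} (default); False draws
        continuous uniforms on [0, n+1].
    """

    q: float = 0.95
    n_trials: int = 10_000
    seed: int = 0
    min_genes_present: int = 5
    integer_null: bool = True

    def __post_init__(self):
        if not 0 < self.q < 1:
            raise ValueError(f"q must be in (0, 1), got {self.q}")
        if self.n_trials < 100:
            raise ValueError(f"n_trials must be >= 100, got {self.n_trials}")
        if self.min_genes_present < 1:
            raise ValueError("min_genes_present must be positive")


def _rng_for_signature(seed: int, signature_id: str) -> np.random.Generator:
    """One RNG stream per (signature, seed): batch order cannot matter."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(signature_id.encode())])


def directed_ranks(
    expr: ExpressionMatrix,
    sig: GeneSignature,
    min_genes_present: int = 5,
) -> pd.DataFrame:
    """Per-gene sample ranks (1..n ascending), down genes ranked on negated values.

    Ties receive average ranks.  Raises :class:`SignatureSkipped` when fewer
    than ``min_genes_present`` signature genes are in the matrix.
    """
    up = sorted(sig.up_genes & set(expr.gene_ids))
    down = sorted(sig.down_genes & set(expr.gene_ids))
    if len(up) + len(down) < min_genes_present:
        raise SignatureSkipped(sig.signature_id, len(up) + len(down), min_genes_present)
    mat = expr.data.loc[up + down].to_numpy(copy=True)
    if down:
        mat[len(up):] *= -1.0
    ranks = rankdata(mat, axis=1, method="average")
    return pd.DataFrame(ranks, index=up + down, columns=expr.sample_ids)


def rank_sum_order(ranks: pd.DataFrame) -> tuple[pd.Series, list]:
    """Sum directed ranks per sample and order samples ascending.

    Equal rank sums are ordered by sample id for determinism.
    """
    sums = ranks.sum(axis=0)
    sums.name = "rank_sum"
    order = sums.to_frame().reset_index(names="sample_id")
    order = order.sort_values(["rank_sum", "sample_id"], kind="stable")
    return sums, order["sample_id"].tolist()


def null_rank_sums(
    n: int,
    k: int,
    cfg: RoiConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Rank sums of ``cfg.n_trials`` artificial patients.

    Each trial draws, independently for each of the k genes, a rank
    uniformly from {0, ..., n+1} (integers by default) and sums the draws.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    if k < 1:
        raise ValueError(f"need k >= 1 genes, got {k}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.integer_null:
        draws = rng.integers(0, n + 2, size=(cfg.n_trials, k))
    else:
        draws = rng.uniform(0.0, n + 1.0, size=(cfg.n_trials, k))
    return draws.sum(axis=1)


def exact_null_pmf(n: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf of the integer null rank sum (support 0..k*(n+1)).

    The sum of k i.i.d. uniforms on {0..n+1} has pmf equal to the k-fold
    convolution of the single-gene pmf; feasible for the small (n, k) used
    to cross-check the sampled null.
    """
    single = np.full(n + 2, 1.0 / (n + 2))
    pmf = single.copy()
    for _ in range(k - 1):
        pmf = np.convolve(pmf, single)
    return np.arange(pmf.size), pmf


def _type1_quantile(sorted_values: np.ndarray, p: float) -> float:
    """Nearest-rank (type-1) empirical quantile: inf{x : F(x) >= p}."""
    m = sorted_values.size
    idx = max(int(np.ceil(p * m)), 1) - 1
    return float(sorted_values[idx])


def compute_region(null_sums: np.ndarray, q: float) -> tuple[float, float]:
    """Symmetric nearest-rank quantile bounds of the null rank sums.

    lower = (1-q)/2 quantile, upper = (1+q)/2 quantile; the closed interval
    [lower, upper] contains at least a fraction q of the trials by the
    nearest-rank construction.
    """
    null_sums = np.asarray(null_sums)
    if null_sums.size == 0:
        raise ValueError("null_sums is empty")
    s = np.sort(null_sums)
    lower = _type1_quantile(s, (1.0 - q) / 2.0)
    upper = _type1_quantile(s, (1.0 + q) / 2.0)
    return lower, upper


def exact_null_region(n: int, k: int, q: float) -> tuple[float, float]:
    """Region bounds from the exactly enumerated integer null distribution."""
    values, pmf = exact_null_pmf(n, k)
    cdf = np.cumsum(pmf)
    lo_p, hi_p = (1.0 - q) / 2.0, (1.0 + q) / 2.0
    lower = values[int(np.searchsorted(cdf, lo_p, side="left"))]
    upper = values[int(np.searchsorted(cdf, hi_p, side="left"))]
    return float(lower), float(upper)


@dataclass
class RoiResult:
    """Cohort partition for one signature, with the null it was judged against."""

    signature_id: str
    rank_sums: pd.Series
    sample_order: list
    null_sums: np.ndarray
    region: tuple[float, float]
    labels: pd.Series
    k_used: int
    q: float
    n_trials: int = field(default=0)

    def label_fractions(self) -> dict:
        n = len(self.labels)
        counts = self.labels.value_counts()
        return {
            lab: float(counts.get(lab, 0)) / n
            for lab in (ClassLabel.LOW, ClassLabel.INDEPENDENT, ClassLabel.HIGH)
        }

    def null_coverage(self) -> float:
        """Fraction of null trials inside the closed region (≈ q by construction)."""
        lo, hi = self.region
        return float(np.mean((self.null_sums >= lo) & (self.null_sums <= hi)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.rank_sums.index,
                "signature_id": self.signature_id,
                "rank_sum": self.rank_sums.to_numpy(),
                "label": [lab.value for lab in self.labels],
            }
        )

    def summary(self) -> str:
        fr = self.label_fractions()
        lo, hi = self.region
        lines = [
            f"ROI_{self.q:g} partition for signature {self.signature_id!r}",
            f"  samples: {len(self.labels)}   signature genes used: {self.k_used}",
            f"  null trials: {len(self.null_sums)}   "
            f"region: [{lo:g}, {hi:g}]   null coverage: {self.null_coverage():.4f}",
            "  class fractions: "
            + "  ".join(f"{lab.value}={fr[lab]:.3f}" for lab in fr),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Null rank-sum histogram with the region and the observed rank sums."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        ax.hist(self.null_sums, bins=60, color="0.7", density=True,
                label="null rank sums")
        lo, hi = self.region
        ax.axvspan(lo, hi, color="tab:blue", alpha=0.15,
                   label=f"ROI$_{{{self.q:g}}}$")
        colors = {ClassLabel.LOW: "tab:cyan", ClassLabel.INDEPENDENT: "0.4",
                  ClassLabel.HIGH: "tab:orange"}
        for lab, color in colors.items():
            xs = self.rank_sums[self.labels == lab]
            ax.plot(xs, np.full(len(xs), -0.0001), "|", color=color,
                    markersize=12, label=lab.value)
        ax.set_xlabel("rank sum")
        ax.set_ylabel("null density")
        ax.legend(loc="upper right", fontsize=8)
        ax.set_title(self.signature_id)
        return ax


def roi_assign(
    expr: ExpressionMatrix,
    sig: GeneSignature,
    cfg: RoiConfig | None = None,
) -> RoiResult:
    """Full ROI_q partition of a cohort for one signature.

    Samples with rank sum strictly below the lower bound are ``low``,
    strictly above the upper bound ``high``, and ``independent`` otherwise
    (boundary-equal sums are conservatively independent).
    """
    cfg = cfg or RoiConfig()
    ranks = directed_ranks(expr, sig, cfg.min_genes_present)
    sums, order = rank_sum_order(ranks)
    rng = _rng_for_signature(cfg.seed, sig.signature_id)
    null = null_rank_sums(expr.n_samples, ranks.shape[0], cfg, rng=rng)
    lo, hi = compute_region(null, cfg.q)
    vals = sums.to_numpy()
    labels = [
        ClassLabel.LOW if v < lo else ClassLabel.HIGH if v > hi else ClassLabel.INDEPENDENT
        for v in vals
    ]
    return RoiResult(
        signature_id=sig.signature_id,
        rank_sums=sums,
        sample_order=order,
        null_sums=null,
        region=(lo, hi),
        labels=pd.Series(labels, index=sums.index, name="label", dtype=object),
        k_used=ranks.shape[0],
        q=cfg.q,
        n_trials=cfg.n_trials,
    )


class SignatureROI:
    """Model-style facade: cohort + signature in, :class:`RoiResult` out.

    Example
    -------
    >>> res = SignatureROI(expr, sig, q=0.95, n_trials=10000).fit(seed=17)
    >>> print(res.summary())
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        signature: GeneSignature,
        q: float = 0.95,
        n_trials: int = 10_000,
        min_genes_present: int = 5,
        integer_null: bool = True,
    ):
        self.expr = expr
        self.signature = signature
        self.q = q
        self.n_trials = n_trials
        self.min_genes_present = min_genes_present
        self.integer_null = integer_null

    def fit(self, seed: int = 0) -> RoiResult:
        cfg = RoiConfig(
            q=self.q,
            n_trials=self.n_trials,
            seed=seed,
            min_genes_present=self.min_genes_present,
            integer_null=self.integer_null,
        )
        return roi_assign(self.expr, self.signature, cfg)
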