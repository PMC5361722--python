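"""Synthetic expression cohorts with planted low/independent/high structure.

The generator emulates the cohort structure the region-of-independence
procedure assumes: for each planted signature, a ``high`` block of samples
whose signature genes are coherently shifted up (down genes shifted down),
a mirror-image ``low`` block, and an ``independent`` block whose signature
genes receive uncorrelated per-gene jitter and hence lose their coherent
ordering.  Background expression is log-normal-like: gene-specific baseline
plus Gaussian noise on the log scale, exponentiated, so raw values resemble
non-negative platform intensities and effect sizes are in units of the
log-scale noise sd.

Multi-dataset and cross-platform variants apply monotone log-scale
distortions; a rank-based method must be invariant to the per-dataset
global ones, while gene-wise offsets and noise perturb within-sample gene
orderings the way a platform change does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSignature
from .roi import ClassLabel

__all__ = [
    "SignatureSpec",
    "PlatformDistortion",
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "simulate_multidataset",
    "simulate_platform_pair",
]


@dataclass(frozen=True)
class SignatureSpec:
    """One planted signature: size k, block fractions, log-scale effect delta (in
    noise-sd units) and the fraction of its genes that are down-directed."""

    signature_id: str
    k: int = 50
    frac_low: float = 0.3
    frac_high: float = 0.3
    delta: float = 2.0
    frac_down: float = 0.0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("signature size k must be >= 1")
        if not (0 <= self.frac_low <= 1 and 0 <= self.frac_high <= 1):
            raise ValueError("block fractions must be in [0, 1]")
        if self.frac_low + self.frac_high > 1 + 1e-12:
            raise ValueError("frac_low + frac_high must be <= 1")
        if self.delta < 0:
            raise ValueError("effect size delta must be >= 0")
        if not 0 <= self.frac_down <= 1:
            raise ValueError("frac_down must be in [0, 1]")


@dataclass(frozen=True)
class PlatformDistortion:
    """Monotone log-scale rendering of a platform.

    ``log_scale``/``log_offset`` form a global (per-profile) affine map on
    the log scale — strictly increasing, so it cannot change within-sample
    gene orderings.  ``gene_scale_sd`` adds gene-wise log offsets and
    ``noise_sd`` i.i.d. log-scale noise; both perturb orderings, emulating a
    real platform switch.
    """

    log_scale: float = 1.0
    log_offset: float = 0.0
    gene_scale_sd: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.log_scale <= 0:
            raise ValueError("log_scale must be > 0 (monotone)")


@dataclass
class SimConfig:
    """Study-condition knobs of the generator (all sizes in samples/genes)."""

    n_samples: int = 500
    n_genes: int = 1000
    signatures: Sequence[SignatureSpec] = field(
        default_factory=lambda: [SignatureSpec("SIG1")]
    )
    noise_sd: float = 1.0
    base_log_mean: float = 6.0
    base_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        needed = sum(s.k for s in self.signatures)
        if needed > self.n_genes:
            raise ValueError(
                f"signatures need {needed} genes but n_genes={self.n_genes}"
            )
        ids = [s.signature_id for s in self.signatures]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate signature ids in SimConfig")


@dataclass
class SimTruth:
    """Planted ground truth: per-sample labels and per-signature gene sets."""

    labels: pd.DataFrame  # samples x signatures, ClassLabel values
    signatures: dict  # signature_id -> GeneSignature

    def labels_for(self, signature_id: str) -> pd.Series:
        return self.labels[signature_id]


def _gene_ids(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"g{str(i).zfill(width)}" for i in range(n)]


def _sample_ids(n: int, prefix: str) -> list:
    width = max(3, len(str(n)))
    return [f"{prefix}{str(i).zfill(width)}" for i in range(n)]


def _block_sizes(n: int, frac_low: float, frac_high: float) -> tuple[int, int]:
    n_low = int(round(n * frac_low))
    n_high = int(round(n * frac_high))
    if n_low + n_high > n:  # rounding overflow on extreme fractions
        n_high = n - n_low
    return n_low, n_high


def _plant_signature(
    log_x: np.ndarray,
    gene_rows: np.ndarray,
    n_down: int,
    spec: SignatureSpec,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shift ``log_x`` in place for one signature; returns per-sample labels."""
    n = log_x.shape[1]
    n_low, n_high = _block_sizes(n, spec.frac_low, spec.frac_high)
    perm = rng.permutation(n)
    low_idx, high_idx = perm[:n_low], perm[n_low : n_low + n_high]
    ind_idx = perm[n_low + n_high :]

    direction = np.ones(len(gene_rows))  # +1 up genes, -1 down genes
    direction[:n_down] = -1.0
    shift = spec.delta * noise_sd
    log_x[np.ix_(gene_rows, high_idx)] += shift * direction[:, None]
    log_x[np.ix_(gene_rows, low_idx)] -= shift * direction[:, None]
    if len(ind_idx) and spec.delta > 0:
        # uncorrelated per-(gene, sample) jitter: variance without coherence
        log_x[np.ix_(gene_rows, ind_idx)] += rng.normal(
            0.0, shift, size=(len(gene_rows), len(ind_idx))
        )

    labels = np.full(n, ClassLabel.INDEPENDENT, dtype=object)
    labels[low_idx] = ClassLabel.LOW
    labels[high_idx] = ClassLabel.HIGH
    return labels


def simulate_cohort(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    sample_prefix: str = "S",
    base_log_means: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate one cohort plus its planted truth.

    Signature gene sets are disjoint consecutive blocks of the gene universe;
    the remaining genes are pure background.  Reproducible: the same config
    (including seed) yields the same matrix.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    samples = _sample_ids(cfg.n_samples, sample_prefix)

    if base_log_means is None:
        base_log_means = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=cfg.n_genes)
    log_x = base_log_means[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples)
    )

    label_cols: dict[str, np.ndarray] = {}
    truth_sigs: dict[str, GeneSignature] = {}
    row = 0
    for spec in cfg.signatures:
        gene_rows = np.arange(row, row + spec.k)
        row += spec.k
        n_down = int(round(spec.k * spec.frac_down))
        sig_genes = [genes[i] for i in gene_rows]
        truth_sigs[spec.signature_id] = GeneSignature(
            signature_id=spec.signature_id,
            up_genes=frozenset(sig_genes[n_down:]),
            down_genes=frozenset(sig_genes[:n_down]),
            source="synthetic",
        )
        label_cols[spec.signature_id] = _plant_signature(
            log_x, gene_rows, n_down, spec, cfg.noise_sd, rng
        )

    expr = ExpressionMatrix(
        pd.DataFrame(np.exp(log_x), index=genes, columns=samples)
    )
    truth = SimTruth(
        labels=pd.DataFrame(label_cols, index=samples),
        signatures=truth_sigs,
    )
    return expr, truth


def simulate_multidataset(
    cfg: SimConfig,
    n_datasets: int,
    samples_per_dataset: Sequence[int] | None = None,
    class_skew: Sequence[tuple[float, float]] | None = None,
    distortions: Sequence[PlatformDistortion] | None = None,
) -> dict:
    """Several cohorts sharing a gene universe and signature truth.

    Each dataset draws fresh samples from the same generative model, with an
    optional per-dataset (frac_low, frac_high) override (``class_skew``) and
    a per-dataset monotone log-scale distortion.  Returns a mapping
    ``dataset_id -> (ExpressionMatrix, SimTruth)``.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    master = np.random.default_rng(cfg.seed)
    base_log_means = master.normal(cfg.base_log_mean, cfg.base_log_sd, size=cfg.n_genes)
    if distortions is None:
        distortions = [
            PlatformDistortion(
                log_scale=float(master.uniform(0.8, 1.25)),
                log_offset=float(master.uniform(-0.5, 0.5)),
            )
            for _ in range(n_datasets)
        ]
    out = {}
    for d in range(n_datasets):
        d_cfg = cfg
        if samples_per_dataset is not None:
            d_cfg = replace(d_cfg, n_samples=samples_per_dataset[d])
        if class_skew is not None:
            fl, fh = class_skew[d]
            d_cfg = replace(
                d_cfg,
                signatures=[
                    replace(s, frac_low=fl, frac_high=fh) for s in d_cfg.signatures
                ],
            )
        rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, d])
        expr, truth = simulate_cohort(
            d_cfg, rng=rng, sample_prefix=f"D{d}_", base_log_means=base_log_means
        )
        dist = distortions[d]
        expr = _apply_distortion(expr, dist, rng)
        out[f"D{d}"] = (expr, truth)
    return out


def _apply_distortion(
    expr: ExpressionMatrix,
    dist: PlatformDistortion,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    log_x = np.log(np.maximum(expr.values, 1e-300))
    log_x = dist.log_scale * log_x + dist.log_offset
    if dist.gene_scale_sd > 0:
        log_x = log_x + rng.normal(0.0, dist.gene_scale_sd, size=(log_x.shape[0], 1))
    if dist.noise_sd > 0:
        log_x = log_x + rng.normal(0.0, dist.noise_sd, size=log_x.shape)
    return ExpressionMatrix(
        pd.DataFrame(np.exp(log_x), index=expr.gene_ids, columns=expr.sample_ids),
        annotations=expr.annotations,
    )


def simulate_platform_pair(
    expr: ExpressionMatrix,
    distortion_a: PlatformDistortion | None = None,
    distortion_b: PlatformDistortion | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two renderings of the same underlying samples on different "platforms".

    With zero gene-wise spread and zero noise the two renderings are
    per-profile monotone transforms of the base cohort, so any rank-in-sample
    method must agree exactly between them.
    """
    distortion_a = distortion_a or PlatformDistortion(log_scale=1.1, log_offset=0.3)
    distortion_b = distortion_b or PlatformDistortion(log_scale=0.9, log_offset=-0.2)
    rng = np.random.default_rng(seed)
    a = _apply_distortion(expr, distortion_a, rng)
    b = _apply_distortion(expr, distortion_b, rng)
    return a, b
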