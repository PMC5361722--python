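"""Core data containers and readers/writers for the standard flat formats.

Expression matrices are delimited text with genes as rows (first column =
gene/probe id, header row = sample ids).  Gene signatures use GMT, with the
``_UP``/``_DN`` stem convention or a two-column sidecar carrying gene
directionality.  Probe-to-gene maps are two-column delimited text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "ProbeMap",
    "ExpressionLoadError",
    "GmtFormatError",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_probe_map",
    "read_annotations",
    "collapse_probes",
    "intersect_genes",
]


class ExpressionLoadError(ValueError):
    """Raised when an expression file fails validation."""


class GmtFormatError(ValueError):
    """Raised on a malformed GMT line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set split into up- and down-directed subsets.

    Genes in ``up_genes`` rise with activation of the underlying process,
    genes in ``down_genes`` fall with it.  Undirected signatures keep every
    gene in ``up_genes``.
    """

    signature_id: str
    up_genes: frozenset = frozenset()
    down_genes: frozenset = frozenset()
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "up_genes", frozenset(self.up_genes))
        object.__setattr__(self, "down_genes", frozenset(self.down_genes))
        if self.up_genes & self.down_genes:
            raise ValueError(
                f"signature {self.signature_id!r}: up/down gene sets overlap: "
                f"{sorted(self.up_genes & self.down_genes)[:5]}"
            )
        if not (self.up_genes | self.down_genes):
            raise ValueError(f"signature {self.signature_id!r} is empty")

    @property
    def genes(self) -> frozenset:
        return self.up_genes | self.down_genes

    def __len__(self) -> int:
        return len(self.genes)


class ExpressionMatrix:
    """Genes x samples matrix of raw non-negative expression.

    Wraps a pandas DataFrame (index = gene ids, columns = sample ids) and
    validates it once at construction: unique sample ids, finite values, no
    negatives.  Duplicate gene rows are only allowed when a probe-collapse
    step will follow (``allow_duplicate_genes=True``).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        annotations: pd.DataFrame | None = None,
        allow_duplicate_genes: bool = False,
    ):
        data = data.copy()
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        if data.columns.duplicated().any():
            dups = data.columns[data.columns.duplicated()].tolist()
            raise ExpressionLoadError(f"duplicated sample ids: {dups[:5]}")
        if not allow_duplicate_genes and data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].tolist()
            raise ExpressionLoadError(f"duplicated gene ids: {dups[:5]}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_non_numeric(data)
            raise ExpressionLoadError(f"non-numeric cell at {bad}")
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ExpressionLoadError(
                f"non-finite value at gene {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ExpressionLoadError(
                f"negative value {values[r, c]} at gene {data.index[r]!r}, "
                f"sample {data.columns[c]!r}"
            )
        self.data = data.astype(float)
        if annotations is not None:
            annotations = annotations.copy()
            annotations.index = annotations.index.astype(str)
        self.annotations = annotations

    @property
    def gene_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[genes], annotations=self.annotations)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[[s for s in samples if s in self.annotations.index]]
        return ExpressionMatrix(self.data[list(samples)], annotations=ann)

    def profile(self, sample_id: str) -> pd.Series:
        """Single-sample expression vector indexed by gene id."""
        return self.data[sample_id]

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


@dataclass
class ProbeMap:
    """Many-to-one probe -> gene id mapping."""

    mapping: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}

    def __getitem__(self, probe: str) -> str:
        return self.mapping[probe]

    def __contains__(self, probe: str) -> bool:
        return probe in self.mapping

    def genes(self) -> set:
        return set(self.mapping.values())


def _first_non_numeric(data: pd.DataFrame) -> str:
    for col in data.columns:
        coerced = pd.to_numeric(data[col], errors="coerce")
        bad = coerced.isna() & data[col].notna()
        if bad.any():
            row = data.index[bad.to_numpy().nonzero()[0][0]]
            return f"gene {row!r}, sample {col!r}"
    return "unknown cell"


def read_expression(
    path,
    sep: str = "\t",
    transposed: bool = False,
    allow_duplicate_genes: bool = False,
    annotations: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression matrix (genes as rows unless ``transposed``).

    Raises :class:`ExpressionLoadError` naming the offending cell on
    non-numeric or negative entries, and on duplicated sample ids.
    """
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # malformed header / unreadable file
        raise ExpressionLoadError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ExpressionLoadError(f"{path}: no sample columns found (malformed header?)")
    if transposed:
        df = df.T
    non_numeric = df.select_dtypes(exclude=[np.number])
    if non_numeric.shape[1]:
        raise ExpressionLoadError(f"{path}: non-numeric cell at {_first_non_numeric(df)}")
    try:
        return ExpressionMatrix(
            df, annotations=annotations, allow_duplicate_genes=allow_duplicate_genes
        )
    except ExpressionLoadError as exc:
        raise ExpressionLoadError(f"{path}: {exc}") from exc


def write_expression(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    expr.data.to_csv(path, sep=sep, index_label="gene_id")


def _split_stem(name: str) -> tuple[str, str | None]:
    upper = name.upper()
    if upper.endswith("_UP"):
        return name[:-3], "up"
    if upper.endswith("_DN") or upper.endswith("_DOWN"):
        return name[: -3 if upper.endswith("_DN") else -5], "down"
    return name, None


def read_gmt(
    path,
    direction_map: Mapping[str, str] | None = None,
    merge_up_dn: bool = True,
) -> list:
    """Parse a GMT file into :class:`GeneSignature` objects.

    ``_UP``/``_DN`` pairs sharing a stem are merged into one directed
    signature.  ``direction_map`` (gene id -> "up"/"down") optionally assigns
    directionality to genes of otherwise undirected signatures; genes of
    unknown direction default to up.
    """
    raw: list[tuple[str, str, list]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}: line {lineno} has {len(fields)} fields (need >= 3)",
                    line_number=lineno,
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            raw.append((name, desc, genes))

    sigs: dict[str, dict] = {}
    order: list[str] = []
    for name, desc, genes in raw:
        stem, direction = _split_stem(name) if merge_up_dn else (name, None)
        if stem not in sigs:
            sigs[stem] = {"source": desc, "up": set(), "down": set()}
            order.append(stem)
        bucket = sigs[stem]
        if direction == "down":
            bucket["down"].update(genes)
        elif direction == "up":
            bucket["up"].update(genes)
        else:
            for g in genes:
                d = (direction_map or {}).get(g, "up")
                bucket["down" if d == "down" else "up"].add(g)
    out = []
    for stem in order:
        b = sigs[stem]
        # a gene listed both up and down (conflicting sources) stays up
        out.append(
            GeneSignature(
                signature_id=stem,
                up_genes=frozenset(b["up"]),
                down_genes=frozenset(b["down"] - b["up"]),
                source=b["source"],
            )
        )
    return out


def write_gmt(signatures: Iterable[GeneSignature], path) -> None:
    """Write signatures in GMT form, splitting directed ones into _UP/_DN lines."""
    with open(path, "w") as fh:
        for sig in signatures:
            if sig.down_genes:
                fh.write(
                    "\t".join([f"{sig.signature_id}_UP", sig.source, *sorted(sig.up_genes)])
                    + "\n"
                )
                fh.write(
                    "\t".join([f"{sig.signature_id}_DN", sig.source, *sorted(sig.down_genes)])
                    + "\n"
                )
            else:
                fh.write(
                    "\t".join([sig.signature_id, sig.source, *sorted(sig.up_genes)]) + "\n"
                )


def read_probe_map(path, sep: str = "\t") -> ProbeMap:
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: probe map needs two columns (probe, gene)")
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    if probes.duplicated().any():
        raise ValueError(f"{path}: probes mapping to multiple genes: "
                         f"{probes[probes.duplicated()].tolist()[:5]}")
    return ProbeMap(dict(zip(probes, genes)))


def read_annotations(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return df


def collapse_probes(
    expr: ExpressionMatrix,
    probe_map: ProbeMap,
    mode: str = "iqr_most_variable",
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    ``iqr_most_variable`` keeps, per gene, the probe with the largest
    interquartile range across samples (cohort-level; used when building the
    region-of-independence gold standard).  ``max_raw_expression`` keeps the
    probe with the highest raw expression — the single profile's own values
    when the matrix has one sample, the per-cohort mean otherwise — and is
    therefore safe to apply to one sample in isolation.  Ties keep the
    lexicographically smallest probe id.
    """
    if mode not in ("iqr_most_variable", "max_raw_expression"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    data = expr.data
    mapped_mask = data.index.isin(probe_map.mapping.keys())
    n_unmapped = int((~mapped_mask).sum())
    if n_unmapped:
        logger.info("collapse_probes: skipping %d unmapped probes", n_unmapped)
    data = data.loc[mapped_mask]
    if data.shape[0] == 0:
        raise ValueError("collapse_probes: zero probes covered by the probe map")

    if mode == "iqr_most_variable":
        stat = pd.Series(
            np.subtract(*np.percentile(data.to_numpy(), [75, 25], axis=1)),
            index=data.index,
        )
    else:
        if data.shape[1] == 1:
            stat = data.iloc[:, 0]
        else:
            stat = data.mean(axis=1)

    genes = pd.Index([probe_map[p] for p in data.index], name="gene_id")
    frame = pd.DataFrame({"gene": genes, "stat": stat.to_numpy()}, index=data.index)
    # sort by (gene, -stat, probe id) and keep the first probe per gene:
    # highest statistic, ties broken by lexicographically smallest probe
    frame = frame.sort_index().sort_values("stat", ascending=False, kind="stable")
    winners = frame.groupby("gene", sort=True).head(1)
    collapsed = data.loc[winners.index]
    collapsed.index = pd.Index(winners["gene"], name="gene_id")
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(collapsed, annotations=expr.annotations)


def intersect_genes(matrices: Sequence[ExpressionMatrix]) -> list:
    """Restrict matrices to their shared gene universe (sorted), returned as new objects.

    Harmonization across platforms is always explicit: callers (e.g. the
    training driver) invoke this once rather than each operation silently
    intersecting.
    """
    if not matrices:
        return []
    common: set = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("intersect_genes: empty shared gene universe")
    ordered = sorted(common)
    return [m.subset_genes(ordered) for m in matrices]
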