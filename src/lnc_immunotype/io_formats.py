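"""Readers, writers and data-preparation steps for the pipeline's table formats.

Expression matrices travel as plain TSV (genes in rows, header row of sample
ids), gene sets as GMT, survival and label tables as headered TSV, and the
pipeline configuration as a flat YAML file mirroring :class:`PipelineConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "SurvivalTable",
    "PipelineConfig",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_survival",
    "write_survival",
    "read_labels",
    "write_labels",
    "drop_all_zero_genes",
    "split_by_annotation",
]

ENDPOINTS = ("OS", "PFS", "DSS")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A gene x sample expression table (TPM, or log2(TPM + offset)).

    ``values`` is a :class:`pandas.DataFrame` whose index holds gene symbols
    and whose columns hold sample identifiers.  Values must be finite, and
    non-negative unless ``log_transformed`` is set.
    """

    values: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if v.columns.has_duplicates:
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        arr = v.to_numpy()
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if not self.log_transformed and arr.size and arr.min() < 0:
            raise ValueError("TPM values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[keep], self.log_transformed)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.log_transformed)


def read_expression(path: str | Path, log_transformed: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV into a validated :class:`ExpressionMatrix`.

    Duplicate gene symbols are collapsed by keeping the row with the highest
    mean expression (logged), matching the usual symbol-collapse convention.
    A malformed numeric cell raises a parse error naming the offending
    row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.empty or raw.shape[1] == 0:
        raise ValueError(f"{path}: empty expression table")
    try:
        num = raw.astype(float)
    except ValueError:
        for col in raw.columns:
            bad = pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()
            if bad.any():
                gene = raw.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"{path}: non-numeric value {raw.loc[gene, col]!r} "
                    f"at gene {gene!r}, sample {col!r}"
                ) from None
        raise
    if num.index.has_duplicates:
        means = num.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="mergesort")
        deduped = num.iloc[order]
        deduped = deduped[~deduped.index.duplicated(keep="first")]
        num = deduped.loc[[g for g in dict.fromkeys(num.index)]]
        logger.info("collapsed duplicate gene ids by highest mean in %s", path)
    num.index = num.index.astype(str)
    num.columns = num.columns.astype(str)
    num.index.name = None
    num.columns.name = None
    return ExpressionMatrix(num, log_transformed=log_transformed)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional hint for the universe size."""

    sets: dict[str, GeneSet] = field(default_factory=dict)
    universe_hint: int | None = None

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if not gs.genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self) -> set:
        out: set = set()
        for gs in self:
            out |= gs.genes
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB gene1 TAB gene2 ...)."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc = parts[0], parts[1]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            genes = frozenset(g for g in parts[2:] if g)
            sets[name] = GeneSet(name, desc, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.description}\t{genes}\n")


# ---------------------------------------------------------------------------
# Survival and label tables
# ---------------------------------------------------------------------------

@dataclass
class SurvivalTable:
    """Rows of (sample_id, time in days, event 0/1, endpoint OS|PFS|DSS)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "time", "event", "endpoint"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"survival table missing columns: {sorted(missing)}")
        d = self.data
        if (d["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not d["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 (censored) or 1 (event)")
        bad = set(d["endpoint"]) - set(ENDPOINTS)
        if bad:
            raise ValueError(f"unknown endpoints: {sorted(bad)}")
        if d.duplicated(["sample_id", "endpoint"]).any():
            raise ValueError("one row per (sample, endpoint) required")

    def endpoint(self, name: str) -> pd.DataFrame:
        if name not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {name!r}")
        return self.data[self.data["endpoint"] == name].reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].unique().tolist()


def read_survival(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    return SurvivalTable(df)


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path, label_col: str = "label") -> pd.Series:
    """Read a two-column sample/label TSV into a Series indexed by sample id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: label table needs sample and label columns")
    sample_col = df.columns[0]
    col = label_col if label_col in df.columns else df.columns[1]
    return df.set_index(sample_col)[col]


def write_labels(labels: pd.Series, path: str | Path,
                 sample_col: str = "sample_id", label_col: str = "label") -> None:
    out = labels.rename(label_col).rename_axis(sample_col).reset_index()
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All thresholds and sampling parameters of the pipeline.

    Defaults are the screens this analysis is conventionally run with
    (correlation cutoffs, lncRES thresholds, the marker-overlap rule, DEG and
    GSEA screens) plus standard practice for the rest (log2 offset,
    permutation and consensus-resampling counts).
    """

    r_min: float = 0.5
    p_max: float = 0.05
    lncres_abs_min: float = 0.995
    lncres_fdr_max: float = 0.05
    min_correlated_mrnas: int = 10
    min_marker_overlap_k: int = 3
    cell_p_max: float = 0.05
    min_enriched_cells: int = 10
    deg_fdr_max: float = 0.05
    fc_min: float = 1.2
    gsea_es_min: float = 0.4
    gsea_p_max: float = 0.05
    gsea_fdr_max: float = 0.25
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    n_resamples: int = 500
    resample_fraction: float = 0.8
    k_min: int = 2
    k_max: int = 6
    consensus_k: int | None = None       # override for choose_k
    consensus_method: str = "kmeans"     # or "hierarchical"
    rng_seed: int = 0
    log2_offset: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.resample_fraction <= 1:
            raise ValueError("resample_fraction must be in (0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        for name in ("r_min", "p_max", "lncres_fdr_max", "cell_p_max",
                     "deg_fdr_max", "gsea_p_max", "gsea_fdr_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.lncres_abs_min < 0 or self.lncres_abs_min > 1:
            raise ValueError("lncres_abs_min must be in [0, 1]")
        if self.log2_offset <= 0:
            raise ValueError("log2_offset must be positive")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def drop_all_zero_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes whose TPM is zero in every sample.

    Genes expressed in at least one sample are kept; the operation is
    idempotent and leaves the sample set untouched.
    """
    if m.log_transformed:
        raise ValueError("drop_all_zero_genes expects raw TPM input")
    keep = (m.values != 0).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d all-zero genes", dropped)
    return ExpressionMatrix(m.values.loc[keep], m.log_transformed)


def split_by_annotation(
    m: ExpressionMatrix, biotype: Mapping[str, str]
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition a matrix into lncRNA and protein-coding (mRNA) sub-matrices.

    Genes annotated ``lncRNA`` go to the first output, ``protein_coding`` to
    the second; genes with another biotype or absent from the map are dropped
    with a warning.
    """
    lnc_genes, mrna_genes, dropped = [], [], []
    for g in m.gene_ids:
        bt = biotype.get(g)
        if bt == "lncRNA":
            lnc_genes.append(g)
        elif bt == "protein_coding":
            mrna_genes.append(g)
        else:
            dropped.append(g)
    if dropped:
        logger.warning(
            "%d genes dropped (unannotated or other biotype)", len(dropped)
        )
    if not lnc_genes:
        logger.warning("annotation produced an empty lncRNA matrix")
    if not mrna_genes:
        logger.warning("annotation produced an empty mRNA matrix")
    lnc = ExpressionMatrix(m.values.loc[lnc_genes], m.log_transformed)
    mrna = ExpressionMatrix(m.values.loc[mrna_genes], m.log_transformed)
    return lnc, mrna


def read_biotype(path: str | Path) -> dict[str, str]:
    """Read a two-column gene/biotype TSV into a plain dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation needs gene and biotype columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
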