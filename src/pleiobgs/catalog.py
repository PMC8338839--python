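"""Parsing and filtering of GWAS-Catalog-style association tables.

The unit of entry is one SNP-trait association row; the unit of analysis is
a *trait locus*: the single best (lowest p-value) association of one mapped
gene -- or intergenic label -- with one trait.  Filtering proceeds in four
stages:

1. completeness: rows missing any required field, or with out-of-range
   numerics, are dropped and counted; non-autosomal rows likewise;
2. significance: associations with ``p > p_max`` (default the genome-wide
   threshold 5e-8; the boundary itself is kept) are removed;
3. representative selection: one SNP per (gene, trait) pair, the one with
   the lowest p-value;
4. trait robustness: traits with too few distinct loci or contributing
   studies are removed entirely.

Traits whose retained gene sets overlap heavily are merged into clusters
(single-linkage on Jaccard similarity), so that near-duplicate phenotypes
do not inflate pleiotropy degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ConfigurationError

__all__ = [
    "CatalogDialect",
    "GWAS_CATALOG_DIALECT",
    "ParseReport",
    "parse_catalog",
    "filter_significant",
    "select_representative",
    "dedupe_loci",
    "filter_traits",
    "cluster_traits",
    "apply_trait_clusters",
]

AUTOSOMES = tuple(str(i) for i in range(1, 23))

REQUIRED_FIELDS = (
    "snp_id", "chrom", "pos", "mapped_gene", "trait",
    "study_id", "p_value", "effect_value", "risk_allele_freq",
)
OPTIONAL_FIELDS = ("effect_kind",)


@dataclass(frozen=True)
class CatalogDialect:
    """Mapping from canonical field names to column names in the input table."""

    columns: Mapping[str, str]

    def column(self, fieldname: str) -> str | None:
        return self.columns.get(fieldname)


#: column names used by the NHGRI-EBI GWAS Catalog association download
GWAS_CATALOG_DIALECT = CatalogDialect({
    "snp_id": "SNPS",
    "chrom": "CHR_ID",
    "pos": "CHR_POS",
    "mapped_gene": "MAPPED_GENE",
    "trait": "DISEASE/TRAIT",
    "study_id": "STUDY ACCESSION",
    "p_value": "P-VALUE",
    "effect_value": "OR or BETA",
    "risk_allele_freq": "RISK ALLELE FREQUENCY",
    "effect_kind": "EFFECT_KIND",
})


@dataclass
class ParseReport:
    n_rows: int = 0
    n_records: int = 0
    n_dropped_incomplete: int = 0
    n_dropped_nonautosomal: int = 0
    warnings: list[str] = field(default_factory=list)


def normalize_chrom(labels: pd.Series) -> pd.Series:
    """Strip a leading 'chr' (any case) and upper-case the remaining label."""
    s = labels.astype("string").str.strip()
    s = s.str.replace(r"(?i)^chr", "", regex=True)
    return s.str.upper()


def _to_float(series: pd.Series) -> pd.Series:
    """Strict round-trip float parsing with NaN for unparseable entries.

    ``pd.to_numeric`` trades the last bits of precision for speed; written
    bundles must read back bit-identically, so valid entries are re-parsed
    through numpy's correctly rounded strtod.
    """
    coerced = pd.to_numeric(series.replace("", pd.NA), errors="coerce")
    ok = coerced.notna()
    exact = coerced.astype(float)
    if ok.any():
        exact[ok] = series[ok].to_numpy(dtype=str).astype(np.float64)
    return exact


def parse_catalog(
    table_path,
    dialect: CatalogDialect = GWAS_CATALOG_DIALECT,
    autosomes_only: bool = True,
) -> tuple[pd.DataFrame, ParseReport]:
    """Read a tab-separated association table into canonical records.

    Returns a DataFrame with one row per complete association record
    (columns: the canonical field names) and a :class:`ParseReport` counting
    dropped rows.  Rows with unparseable numerics in required fields are
    dropped, not fatal; a missing required *column* is a configuration error.
    """
    report = ParseReport()
    raw = pd.read_csv(table_path, sep="\t", dtype=str, keep_default_na=False)
    for fieldname in REQUIRED_FIELDS:
        col = dialect.column(fieldname)
        if col is None or col not in raw.columns:
            raise ConfigurationError(
                f"catalog table {table_path} lacks required column "
                f"{col or '<unmapped>'!r} (field {fieldname!r})")
    report.n_rows = len(raw)
    if not len(raw):
        report.warnings.append(f"catalog table {table_path} contains no rows")
        warnings.warn(report.warnings[-1])

    df = pd.DataFrame({f: raw[dialect.column(f)] for f in REQUIRED_FIELDS})
    kind_col = dialect.column("effect_kind")
    if kind_col is not None and kind_col in raw.columns:
        kind = raw[kind_col].str.strip().str.lower()
        kind = kind.replace({"or": "odds_ratio", "odds ratio": "odds_ratio", "": pd.NA})
        df["effect_kind"] = kind
    else:
        df["effect_kind"] = pd.NA

    for col in ("p_value", "effect_value", "risk_allele_freq"):
        df[col] = _to_float(df[col])
    df["pos"] = pd.to_numeric(df["pos"].replace("", pd.NA), errors="coerce")
    df["chrom"] = normalize_chrom(df["chrom"])
    for col in ("snp_id", "mapped_gene", "trait", "study_id"):
        df[col] = df[col].astype("string").str.strip()

    ok = (
        df["p_value"].gt(0) & df["p_value"].le(1)
        & df["risk_allele_freq"].gt(0) & df["risk_allele_freq"].lt(1)
        & df["effect_value"].notna()
        & df["pos"].ge(1)
        & df["chrom"].notna() & (df["chrom"] != "")
        & (df["snp_id"] != "") & (df["mapped_gene"] != "")
        & (df["trait"] != "") & (df["study_id"] != "")
    )
    # an odds ratio must be positive; betas may carry sign
    ok &= ~((df["effect_kind"] == "odds_ratio") & df["effect_value"].le(0))
    ok = ok.fillna(False)
    report.n_dropped_incomplete = int((~ok).sum())
    df = df[ok]

    if autosomes_only:
        auto = df["chrom"].isin(AUTOSOMES)
        report.n_dropped_nonautosomal = int((~auto).sum())
        df = df[auto]

    df = df.reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    report.n_records = len(df)
    return df, report


def filter_significant(records: pd.DataFrame, p_max: float = 5e-8) -> pd.DataFrame:
    """Keep genome-wide-significant records; ``p == p_max`` survives."""
    return records[records["p_value"] <= p_max].reset_index(drop=True)


def _effect_magnitude(df: pd.DataFrame, value_col: str) -> np.ndarray:
    """|effect| on a comparable scale: |log OR| for odds ratios, |beta| else."""
    v = df[value_col].to_numpy(dtype=float)
    mag = np.abs(v)
    is_or = (df.get("effect_kind") == "odds_ratio").to_numpy() if "effect_kind" in df else np.zeros(len(df), bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        mag = np.where(is_or & (v > 0), np.abs(np.log(v)), mag)
    return mag


def _take_best(df: pd.DataFrame, group_cols: list[str], value_col: str) -> pd.DataFrame:
    """One row per group: lowest p, ties by larger |effect|, then snp_id."""
    order = df.assign(
        _mag=-_effect_magnitude(df, value_col)
    ).sort_values(
        ["p_value", "_mag", "snp_id"], kind="mergesort"
    ).drop(columns="_mag")
    best = order.drop_duplicates(subset=group_cols, keep="first")
    return best.sort_values(group_cols, kind="mergesort").reset_index(drop=True)


def select_representative(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse records to one trait locus per (mapped gene, trait) pair.

    The retained SNP is the one with the lowest p-value; ties are broken by
    larger absolute effect and then lexicographic SNP id, so the result does
    not depend on input row order.  Adds ``locus_id`` (the mapped gene or
    intergenic label verbatim) and ``maf = min(q, 1-q)``.
    """
    best = _take_best(records, ["mapped_gene", "trait"], "effect_value")
    best = best.rename(columns={"mapped_gene": "locus_id"})
    q = best["risk_allele_freq"].to_numpy(dtype=float)
    best["maf"] = np.minimum(q, 1.0 - q)
    return best


def dedupe_loci(loci: pd.DataFrame) -> pd.DataFrame:
    """Re-apply representative selection on a trait-locus table.

    Needed after trait clustering, when two member traits of one cluster may
    contribute the same locus.
    """
    value_col = "beta_liability" if "beta_liability" in loci else "effect_value"
    return _take_best(loci, ["locus_id", "trait"], value_col)


def filter_traits(
    loci: pd.DataFrame,
    significant_records: pd.DataFrame,
    min_genes: int = 30,
    min_studies: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop traits with a thin genetic background.

    A trait is kept when it has at least ``min_genes`` distinct loci (after
    representative selection) and at least ``min_studies`` distinct studies
    among its genome-wide-significant records (before locus deduplication).
    Returns the filtered loci and the sorted list of retained trait labels.
    """
    gene_counts = loci.groupby("trait")["locus_id"].nunique()
    study_counts = significant_records.groupby("trait")["study_id"].nunique()
    kept = sorted(
        t for t, n in gene_counts.items()
        if n >= min_genes and study_counts.get(t, 0) >= min_studies
    )
    out = loci[loci["trait"].isin(kept)].reset_index(drop=True)
    return out, kept


def jaccard(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def cluster_traits(loci: pd.DataFrame, overlap_threshold: float = 0.5) -> dict[str, str]:
    """Merge traits with highly overlapping gene sets.

    Traits whose retained gene sets have Jaccard similarity at or above the
    threshold are joined transitively (single linkage); every trait maps to
    its cluster label, the lexicographically smallest member trait.
    """
    if not 0.0 < overlap_threshold <= 1.0:
        raise ConfigurationError(
            f"overlap threshold must lie in (0,1], got {overlap_threshold!r}")
    traits = sorted(loci["trait"].unique())
    gene_sets = {t: set(loci.loc[loci["trait"] == t, "locus_id"]) for t in traits}
    n = len(traits)
    rows, cols = [], []
    for i, j in combinations(range(n), 2):
        if jaccard(gene_sets[traits[i]], gene_sets[traits[j]]) >= overlap_threshold:
            rows += [i, j]
            cols += [j, i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    mapping: dict[str, str] = {}
    for comp in np.unique(labels):
        members = [traits[i] for i in np.flatnonzero(labels == comp)]
        rep = min(members)
        for m in members:
            mapping[m] = rep
    return mapping


def apply_trait_clusters(loci: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Relabel traits by cluster and re-deduplicate per (locus, cluster)."""
    out = loci.copy()
    out["trait"] = out["trait"].map(lambda t: mapping.get(t, t))
    return dedupe_loci(out)
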