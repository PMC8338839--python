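"""End-to-end orchestration: parse -> filter -> convert -> degrees -> annotate -> regress.

The run produces three analysis blocks, mirroring how results are usually
reported for this kind of study:

1. degree summaries and regressions of effect size, within-locus SD, MAF
   and heritability contribution on the degree of pleiotropy;
2. the regression of the recombination covariate on degree;
3. the simple and partial regressions of the B statistic on degree (and
   recombination), with and without the MHC window masked.

Every stage logs its input/output cardinality into a provenance block, so
summary fractions ("x% of loci are pleiotropic") are derivable from any
run.  Reports are plain TSV and text; re-running with the same config is
bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from . import catalog as cat
from . import effects as eff
from . import pleiotropy as pleio
from . import regress
from . import tracks
from .errors import ConfigurationError, InsufficientDataError, PleiobgsError

__all__ = ["RunConfig", "RunResult", "run_analysis", "run_region_analysis"]


@dataclass
class RunConfig:
    """Paths and thresholds of one analysis run."""

    catalog: str | Path
    genes: str | Path | None = None
    b_track: str | Path | None = None
    genetic_map: str | Path | None = None
    regions: str | Path | None = None
    prevalence: str | Path | Mapping[str, float] | None = None
    domains: str | Path | Mapping[str, str] | None = None

    gene_format: str = "bed"
    p_max: float = 5e-8
    min_genes: int = 30
    min_studies: int = 3
    cluster_threshold: float = 0.5
    level: str = "gene"
    rr_log: bool = True
    rr_floor: float = tracks.RR_LOG_FLOOR
    b_scale: float | None = None
    mask_mhc: bool = True
    autosomes_only: bool = True
    region_degree_column: str = "degree"
    out_dir: str | Path | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError("unknown config keys: " + ", ".join(sorted(unknown)))
        return cls(**data)


@dataclass
class RunResult:
    loci: pd.DataFrame
    observations: pd.DataFrame
    profiles: pd.DataFrame
    degree_summary: pd.DataFrame
    degree_fits: dict
    rr_fit: dict
    bgs_fits: dict
    domain_summary: pd.DataFrame | None
    counts: dict = field(default_factory=dict)
    annotated: pd.DataFrame | None = None


def _load_mapping(source, value_cast=float) -> dict:
    """A {key: value} mapping from a dict, YAML file or 2-column TSV."""
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return {str(k): value_cast(v) for k, v in source.items()}
    path = Path(source)
    if path.suffix in (".yaml", ".yml", ".json"):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return {str(k): value_cast(v) for k, v in data.items()}
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ConfigurationError(f"{path}: mapping table needs two columns")
    return {str(k): value_cast(v) for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


class _Stage:
    """Context manager prefixing stage names onto propagated errors."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, PleiobgsError) and not str(exc).startswith("[stage"):
            exc.args = (f"[stage {self.name}] {exc}",)
        return False


def _maybe_result(fn, *args, **kwargs):
    """Run a regression, returning None (with the reason) when data are too thin."""
    try:
        return fn(*args, **kwargs)
    except InsufficientDataError as exc:
        return {"skipped": str(exc)}


def _require_paths(config: RunConfig, keys: tuple[str, ...]) -> None:
    for key in keys:
        value = getattr(config, key)
        if value is not None and not isinstance(value, Mapping) and not Path(value).exists():
            raise ConfigurationError(f"input path for {key!r} does not exist: {value}")


def run_analysis(config: RunConfig) -> RunResult:
    """Execute the full pipeline described in the module docstring."""
    counts: dict = {}
    _require_paths(config, ("catalog", "genes", "b_track", "genetic_map"))

    with _Stage("parse"):
        records, report = cat.parse_catalog(config.catalog, autosomes_only=config.autosomes_only)
        counts["input_rows"] = report.n_rows
        counts["parsed_records"] = report.n_records
        counts["dropped_incomplete"] = report.n_dropped_incomplete
        counts["dropped_nonautosomal"] = report.n_dropped_nonautosomal

    with _Stage("significance"):
        significant = cat.filter_significant(records, p_max=config.p_max)
        counts["significant_records"] = len(significant)

    with _Stage("representative"):
        loci = cat.select_representative(significant)
        counts["trait_loci"] = len(loci)

    with _Stage("trait_filter"):
        loci, kept_traits = cat.filter_traits(
            loci, significant, min_genes=config.min_genes, min_studies=config.min_studies)
        counts["trait_loci_after_trait_filter"] = len(loci)
        counts["traits_kept"] = len(kept_traits)

    with _Stage("convert"):
        prevalence = _load_mapping(config.prevalence, float)
        loci = eff.convert_effects(loci, prevalence)

    with _Stage("cluster"):
        mapping = cat.cluster_traits(loci, overlap_threshold=config.cluster_threshold)
        loci = cat.apply_trait_clusters(loci, mapping)
        counts["trait_clusters"] = len(set(mapping.values()))
        counts["trait_loci_after_clustering"] = len(loci)

    with _Stage("degrees"):
        observations = pleio.observation_table(loci)
        profiles = pleio.assign_degrees(loci)
        counts["loci"] = len(profiles)
        counts["pleiotropic_loci"] = int((profiles["degree"] >= 2).sum())
        degree_summary = pleio.summarize_by_degree(observations)

    with _Stage("degree_fits"):
        degree_fits = {
            "effect_degree": _maybe_result(
                regress.ols_simple, observations["effect_hom"], observations["degree"],
                name="degree"),
            "maf_degree": _maybe_result(
                regress.ols_simple, profiles["maf"], profiles["degree"], name="degree"),
            "h2_degree": _maybe_result(
                regress.ols_simple, observations["h2"], observations["degree"], name="degree"),
        }
        sd_rows = degree_summary.dropna(subset=["mean_within_locus_sd"])
        if len(sd_rows) >= 3 and sd_rows["degree"].nunique() >= 2:
            degree_fits["sd_degree"] = _maybe_result(
                regress.ols_simple, sd_rows["mean_within_locus_sd"], sd_rows["degree"],
                name="degree")
        else:
            degree_fits["sd_degree"] = {"skipped": "fewer than 3 degree classes with a defined SD"}

    domain_map = _load_mapping(config.domains, str)
    domain_table = None
    if domain_map:
        with _Stage("domains"):
            domain_table = pleio.domain_summary(observations, domain_map)

    annotated = None
    rr_fit: dict = {}
    bgs_fits: dict = {}
    if config.b_track and config.genetic_map:
        with _Stage("tracks"):
            b_track = tracks.read_bedgraph(config.b_track, value_kind="B", b_scale=config.b_scale)
            rr_track = tracks.read_genetic_map(config.genetic_map)
            genes = None
            if config.level == "gene":
                if not config.genes:
                    raise ConfigurationError("gene-level analysis requires a gene interval file")
                genes = tracks.read_gene_intervals(config.genes, fmt=config.gene_format)

        with _Stage("annotate"):
            annotated = tracks.annotate(
                profiles, b_track, rr_track, level=config.level, genes=genes,
                rr_floor=config.rr_floor)
            counts["annotated_complete"] = int(annotated["complete"].sum())
            masked = annotated
            if config.level == "gene":
                masked = annotated.rename(columns={"span_start": "start", "span_end": "end"})
            masked, n_removed = tracks.mhc_mask(masked)
            counts["mhc_removed"] = n_removed

        with _Stage("regress"):
            bgs_fits["unmasked"] = _maybe_result(regress.degree_regressions, annotated,
                                             rr_log=config.rr_log)
            bgs_fits["masked"] = _maybe_result(regress.degree_regressions, masked,
                                           rr_log=config.rr_log)
            active = masked if config.mask_mhc else annotated
            active_block = bgs_fits["masked" if config.mask_mhc else "unmasked"]
            if isinstance(active_block, dict) and "skipped" not in active_block:
                rr_fit["rr_degree"] = active_block["simple_rr_degree"]
            else:
                rr_fit["rr_degree"] = None
            counts["regression_rows"] = int(active["complete"].sum()) if "complete" in active else len(active)

    result = RunResult(
        loci=loci, observations=observations, profiles=profiles,
        degree_summary=degree_summary, degree_fits=degree_fits, rr_fit=rr_fit, bgs_fits=bgs_fits,
        domain_summary=domain_table, counts=counts, annotated=annotated)

    if config.out_dir is not None:
        _write_report(config, result)
    return result


def run_region_analysis(config: RunConfig) -> dict:
    """Annotate a pleiotropic-region table with B/RR and run the regressions.

    The region table must carry chrom/start/end/label columns and the degree
    column named by ``config.region_degree_column`` (e.g. a median or
    maximal per-region degree).
    """
    if not config.regions:
        raise ConfigurationError("region analysis requires a region table path")
    _require_paths(config, ("regions", "b_track", "genetic_map"))
    regions = pd.read_csv(config.regions, sep="\t")
    required = {"chrom", "start", "end", config.region_degree_column}
    missing = required - set(regions.columns)
    if missing:
        raise ConfigurationError(
            f"region table {config.regions} lacks column(s): {', '.join(sorted(missing))}")
    regions = regions.rename(columns={config.region_degree_column: "degree"})
    regions["chrom"] = cat.normalize_chrom(regions["chrom"]).astype(str)

    b_track = tracks.read_bedgraph(config.b_track, value_kind="B", b_scale=config.b_scale)
    rr_track = tracks.read_genetic_map(config.genetic_map)
    annotated = tracks.annotate(regions, b_track, rr_track, level="region",
                                rr_floor=config.rr_floor)
    masked, n_removed = tracks.mhc_mask(annotated)
    active = masked if config.mask_mhc else annotated
    results = regress.degree_regressions(active, rr_log=config.rr_log)
    return {
        "annotated": annotated,
        "masked": masked,
        "n_mhc_removed": n_removed,
        "regressions": results,
    }


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _result_rows(analysis: str, res) -> list[dict]:
    if res is None or isinstance(res, dict):
        return []
    rows = []
    for i, term in enumerate(res.names):
        rows.append({
            "analysis": analysis, "term": term,
            "estimate": float(res.coef[i]), "se": float(res.se[i]),
            "t": float(res.t[i]), "p": float(res.p[i]),
            "r2": res.r2, "F": res.f, "df1": res.df_model, "df2": res.df_resid,
            "overall_p": res.f_pvalue, "n": res.n,
        })
    return rows


def _write_report(config: RunConfig, result: RunResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        def _emit(name, df):
            p = out / name
            df.to_csv(p, sep="\t", index=False)
            written.append(p)

        _emit("trait_loci.tsv", result.loci)
        _emit("observations.tsv", result.observations)
        _emit("profiles.tsv", result.profiles)
        _emit("degree_summary.tsv", result.degree_summary)
        if result.domain_summary is not None:
            _emit("domain_summary.tsv", result.domain_summary)
        if result.annotated is not None:
            _emit("annotated.tsv", result.annotated)

        rows = []
        for name, res in result.degree_fits.items():
            rows += _result_rows(f"degree/{name}", res)
        for variant, block in result.bgs_fits.items():
            if isinstance(block, dict) and "skipped" not in block:
                rows += _result_rows(f"bgs/{variant}/simple", block["simple_b_degree"])
                rows += _result_rows(f"rr/{variant}/rr_degree", block["simple_rr_degree"])
                rows += _result_rows(f"bgs/{variant}/partial", block["partial"])
        _emit("regressions.tsv", pd.DataFrame(rows))

        inputs = {}
        for key in ("catalog", "genes", "b_track", "genetic_map", "regions"):
            path = getattr(config, key)
            if path and not isinstance(path, Mapping) and Path(path).exists():
                inputs[key] = {"path": str(path), "sha256": _sha256(path)}
        cfg_echo = {k: (str(v) if isinstance(v, Path) else v)
                    for k, v in asdict(config).items()
                    if not isinstance(v, Mapping)}
        prov = {
            "version": __version__,
            "config": cfg_echo,
            "inputs": inputs,
            "counts": result.counts,
        }
        p = out / "provenance.json"
        p.write_text(json.dumps(prov, sort_keys=True, indent=1, default=str) + "\n")
        written.append(p)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
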