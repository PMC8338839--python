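"""Seeded synthetic input bundles with planted, recoverable parameters.

The generator emulates the statistical structure of a curated GWAS-catalog
analysis: a small genome of autosome analogues (including a chromosome-6
analogue carrying the 25-34 Mb MHC window), non-overlapping genes, and one
association record per (gene, trait) pair.  Four relationships are planted
and written to a machine-readable truth file so every pipeline stage has a
recovery test:

* homozygous effect size increases linearly with pleiotropy degree
  (slope ``effect_slope``),
* MAF increases linearly with degree (slope ``maf_slope``),
* the B statistic decreases with degree net of recombination
  (partial slope ``b_degree_slope``) and increases with log10(RR)
  (``b_rr_slope``),
* recombination rate is independent of degree.

Degrees follow a truncated geometric law (fewer loci at higher degrees).
Each gene carries one SNP per associated trait at distinct positions; no
linkage disequilibrium, ascertainment or population structure is modelled.
B and RR are piecewise-constant over each gene body, with independent
baseline segments filling the rest of the genome, so interval means have
closed-form truth.  Odds-ratio traits receive odds ratios obtained by
numerically inverting the liability-threshold conversion at the planted
per-allele effect, which makes the planted effect exactly recoverable.

To exercise the filters, the bundle also plants: duplicate SNPs per
(gene, trait) with higher p-values, non-significant rows (p > 5e-8), and
"noise" traits backed by too few genes and studies to survive the trait
robustness filter.  None of these enter the truth tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from . import effects as eff
from .errors import ConfigurationError, NumericalError

__all__ = [
    "GeneratorConfig",
    "generate_tables",
    "generate_bundle",
    "generate_or_effects",
    "simulate_region_table",
]

DOMAIN_NAMES = (
    "cardiovascular", "dermatological", "endocrine", "gastrointestinal",
    "hematological", "immunological", "metabolic", "neurological",
    "respiratory", "skeletal",
)


@dataclass
class GeneratorConfig:
    """Planted parameters and layout of a synthetic bundle.

    Defaults describe a desk-scale analogue of a curated catalog analysis:
    41 robust traits, a truncated-geometric degree law capped at 12, and
    planted slopes in the magnitude range observed for real trait panels
    (effect ~ 0.035 per degree, MAF ~ 0.006 per degree, B ~ -0.02 per degree
    and ~ +0.15 per log10 cM/Mb).  Noise scales are chosen so that planted
    linear laws stay inside their natural ranges (B in [0,1], MAF in
    (0, 0.5]) essentially always, keeping clipping bias negligible.
    """

    seed: int = 0
    n_traits: int = 41
    n_noise_traits: int = 3
    n_genes: int = 2000
    chrom_lengths: tuple = (
        ("1", 50_000_000), ("2", 50_000_000), ("3", 50_000_000),
        ("4", 50_000_000), ("5", 50_000_000), ("6", 50_000_000),
    )
    gene_length: int = 20_000
    # degree law: P(d) proportional to ratio**(d-1), d = 1..max_degree
    degree_ratio: float = 0.5
    max_degree: int = 12
    # homozygous effect |2 beta| = a0 + a1 * degree + N(0, sd)
    effect_intercept: float = 0.2
    effect_slope: float = 0.035
    effect_sd: float = 0.05
    # per-gene MAF = m0 + m1 * degree + N(0, sd), clipped to (0, 0.5]
    maf_intercept: float = 0.15
    maf_slope: float = 0.006
    maf_sd: float = 0.04
    # dichotomous traits: fraction reported as odds ratios, prevalence range
    frac_or_traits: float = 0.5
    prevalence_range: tuple = (0.01, 0.2)
    # per-gene B = c0 + c1 * degree + c2 * log10(RR) + N(0, sd), clipped [0,1]
    b_intercept: float = 0.75
    b_degree_slope: float = -0.02
    b_rr_slope: float = 0.15
    b_sd: float = 0.03
    # inter-gene baseline B segments (bulk of the genome)
    b_background_mean: float = 0.77
    b_background_sd: float = 0.05
    # log10 recombination rate ~ N(mu, sd), truncated at 3.5 sd
    rr_log10_mean: float = 0.0
    rr_log10_sd: float = 0.4
    # filter-exercise fractions
    frac_nonsignificant: float = 0.10
    frac_duplicate: float = 0.15
    # -log10 p of significant associations drawn uniformly on this range
    sig_p_exponent_range: tuple = (8.5, 20.0)

    def validate(self) -> None:
        if self.max_degree < 1 or self.max_degree > self.n_traits:
            raise ConfigurationError(
                f"max_degree must lie in [1, n_traits]={self.n_traits}, got {self.max_degree}")
        if self.n_genes < 1 or self.n_traits < 1:
            raise ConfigurationError("n_genes and n_traits must be positive")
        if not 0.0 < self.degree_ratio <= 1.0:
            raise ConfigurationError("degree_ratio must lie in (0, 1]")
        for label, length in self.chrom_lengths:
            if length <= self.gene_length:
                raise ConfigurationError(f"chromosome {label} shorter than a gene")


def _truncated_geometric(rng, n, ratio, dmax):
    w = ratio ** np.arange(dmax, dtype=float)
    w /= w.sum()
    return rng.choice(np.arange(1, dmax + 1), size=n, p=w)


def _truncated_normal(rng, mean, sd, n, lo_sd=-3.5, hi_sd=3.5):
    return truncnorm.rvs(lo_sd, hi_sd, loc=mean, scale=sd, size=n, random_state=rng)


def generate_or_effects(beta: float, q: float, K: float) -> float:
    """Odds ratio whose liability-threshold conversion yields ``beta``.

    The exact numerical inverse of :func:`pleiobgs.effects.liability_effect`
    in OR at fixed (q, K): converting the returned odds ratio back recovers
    the planted per-allele effect to solver precision.  ``beta = 0`` maps to
    OR = 1 and negative effects to OR < 1.
    """
    if beta == 0.0:
        return 1.0
    out = _or_for_effects(np.array([beta]), np.array([q]), np.array([K]))
    return float(out[0])


def _or_for_effects(beta, q, K, lo=-12.0, hi=12.0, iters=70):
    """Vectorised bisection on log(OR): liability_effect is increasing in OR."""
    beta = np.asarray(beta, dtype=float)
    q = np.asarray(q, dtype=float)
    K = np.asarray(K, dtype=float)
    blo = eff.liability_effect_array(np.exp(lo), q, K)
    bhi = eff.liability_effect_array(np.exp(hi), q, K)
    if np.any(beta < blo) or np.any(beta > bhi):
        raise NumericalError("planted liability effect outside the feasible odds-ratio range")
    u_lo = np.full(beta.shape, lo)
    u_hi = np.full(beta.shape, hi)
    for _ in range(iters):
        mid = 0.5 * (u_lo + u_hi)
        bmid = eff.liability_effect_array(np.exp(mid), q, K)
        high = bmid > beta
        u_hi = np.where(high, mid, u_hi)
        u_lo = np.where(high, u_lo, mid)
    out = np.exp(0.5 * (u_lo + u_hi))
    return np.where(beta == 0.0, 1.0, out)


def _place_genes(cfg: GeneratorConfig, rng) -> pd.DataFrame:
    """Non-overlapping gene spans, spread evenly with seeded jitter."""
    lengths = np.array([ln for _, ln in cfg.chrom_lengths], dtype=float)
    counts = np.floor(cfg.n_genes * lengths / lengths.sum()).astype(int)
    # distribute the remainder deterministically, largest chromosomes first
    for i in np.argsort(-lengths, kind="stable")[: cfg.n_genes - counts.sum()]:
        counts[i] += 1
    rows = []
    gid = 0
    for (label, length), n_c in zip(cfg.chrom_lengths, counts):
        if n_c == 0:
            continue
        slot = length // n_c
        jitter = rng.integers(0, max(1, slot - cfg.gene_length), size=n_c)
        for i in range(n_c):
            start = int(slot * i + jitter[i])
            rows.append((f"GENE{gid:05d}", str(label), start, start + cfg.gene_length))
            gid += 1
    return pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end"])


def generate_tables(cfg: GeneratorConfig) -> dict:
    """Build every bundle table in memory; see :func:`generate_bundle`."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    traits = [f"TRAIT{i:03d}" for i in range(cfg.n_traits)]
    noise_traits = [f"NOISYTRAIT{i:02d}" for i in range(cfg.n_noise_traits)]
    n_or = int(round(cfg.frac_or_traits * cfg.n_traits))
    or_traits = sorted(str(t) for t in rng.choice(traits, size=n_or, replace=False))
    k_lo, k_hi = cfg.prevalence_range
    prevalence = {t: float(rng.uniform(k_lo, k_hi)) for t in or_traits}
    domains = {t: DOMAIN_NAMES[i % len(DOMAIN_NAMES)]
               for i, t in enumerate(traits + noise_traits)}
    study_pools = {t: [f"GCST{i:03d}{j}" for j in range(int(rng.integers(3, 7)))]
                   for i, t in enumerate(traits)}

    genes = _place_genes(cfg, rng)
    n_genes = len(genes)
    degrees = _truncated_geometric(rng, n_genes, cfg.degree_ratio, cfg.max_degree)

    # per-gene latent values
    maf = np.clip(
        cfg.maf_intercept + cfg.maf_slope * degrees
        + rng.normal(0.0, cfg.maf_sd, n_genes),
        1e-3, 0.5)
    log10rr_gene = _truncated_normal(rng, cfg.rr_log10_mean, cfg.rr_log10_sd, n_genes)
    rr_gene = 10.0 ** log10rr_gene
    b_gene = np.clip(
        cfg.b_intercept + cfg.b_degree_slope * degrees
        + cfg.b_rr_slope * log10rr_gene + rng.normal(0.0, cfg.b_sd, n_genes),
        0.0, 1.0)

    mhc_chrom, mhc_lo, mhc_hi = "6", 25_000_000, 34_000_000
    in_mhc = ((genes["chrom"] == mhc_chrom)
              & (genes["start"] < mhc_hi) & (genes["end"] > mhc_lo - 1))

    truth_loci = genes.assign(
        degree=degrees, maf=maf, b_true=b_gene, rr_true=rr_gene,
        log10rr_true=log10rr_gene, in_mhc=in_mhc.to_numpy())

    # one observation per (gene, trait); SNPs at distinct in-gene offsets
    obs_rows = []
    snp_counter = 0
    trait_obs_count = {t: 0 for t in traits}
    for g in range(n_genes):
        d = int(degrees[g])
        chosen = sorted(rng.choice(cfg.n_traits, size=d, replace=False))
        offsets = rng.choice(cfg.gene_length, size=d, replace=False)
        for trait_idx, off in zip(chosen, offsets):
            t = traits[trait_idx]
            pool = study_pools[t]
            study = pool[trait_obs_count[t] % len(pool)]
            trait_obs_count[t] += 1
            obs_rows.append((genes.at[g, "locus_id"], t, f"rs{snp_counter:07d}",
                             genes.at[g, "chrom"], int(genes.at[g, "start"]) + int(off) + 1,
                             study, g))
            snp_counter += 1
    obs = pd.DataFrame(obs_rows, columns=[
        "locus_id", "trait", "snp_id", "chrom", "pos", "study_id", "gene_idx"])
    n_obs = len(obs)

    d_obs = degrees[obs["gene_idx"].to_numpy()]
    hom = cfg.effect_intercept + cfg.effect_slope * d_obs + rng.normal(0.0, cfg.effect_sd, n_obs)
    sign = rng.choice([-1.0, 1.0], size=n_obs)
    beta_true = sign * hom / 2.0
    maf_obs = maf[obs["gene_idx"].to_numpy()]
    flip = rng.random(n_obs) < 0.5
    q_reported = np.where(flip, 1.0 - maf_obs, maf_obs)
    p_exp = rng.uniform(*cfg.sig_p_exponent_range, size=n_obs)
    p_value = 10.0 ** (-p_exp)

    obs["effect_kind"] = np.where(pd.Series(obs["trait"]).isin(or_traits), "odds_ratio", "beta")
    obs["risk_allele_freq"] = q_reported
    obs["p_value"] = p_value
    obs["hom_effect_true"] = hom
    obs["beta_true"] = beta_true
    effect_value = beta_true.copy()
    is_or = (obs["effect_kind"] == "odds_ratio").to_numpy()
    if is_or.any():
        effect_value[is_or] = _or_for_effects(
            beta_true[is_or], q_reported[is_or],
            obs.loc[is_or, "trait"].map(prevalence).to_numpy(dtype=float))
    obs["effect_value"] = effect_value
    obs["h2_true"] = 2.0 * beta_true ** 2 * q_reported * (1.0 - q_reported)

    catalog_cols = ["snp_id", "chrom", "pos", "locus_id", "trait", "study_id",
                    "p_value", "effect_kind", "effect_value", "risk_allele_freq"]
    extra_frames = []

    # duplicate SNPs: a second, less significant SNP for a random subset of pairs
    dup_mask = rng.random(n_obs) < cfg.frac_duplicate
    dup = obs.loc[dup_mask, catalog_cols + ["gene_idx"]].copy()
    if len(dup):
        dup["snp_id"] = [f"rs{snp_counter + i:07d}" for i in range(len(dup))]
        dup["pos"] = dup["pos"] + rng.integers(1, 200, size=len(dup))
        dup["p_value"] = dup["p_value"] * 10.0  # still genome-wide significant
        snp_counter += len(dup)
        extra_frames.append(dup[catalog_cols])

    # non-significant rows exercising the p-value filter
    n_ns = int(round(cfg.frac_nonsignificant * n_obs))
    if n_ns:
        g_idx = rng.integers(0, n_genes, size=n_ns)
        t_idx = rng.integers(0, cfg.n_traits, size=n_ns)
        ns_traits = [traits[i] for i in t_idx]
        ns_kind = np.array(["odds_ratio" if t in or_traits else "beta" for t in ns_traits])
        ns_hom = cfg.effect_intercept + rng.normal(0.0, cfg.effect_sd, n_ns)
        ns_beta = rng.choice([-1.0, 1.0], size=n_ns) * np.abs(ns_hom) / 2.0
        ns_q = np.clip(rng.uniform(0.05, 0.95, size=n_ns), 1e-3, 1 - 1e-3)
        ns_val = ns_beta.copy()
        ns_or_mask = ns_kind == "odds_ratio"
        if ns_or_mask.any():
            ns_val[ns_or_mask] = _or_for_effects(
                ns_beta[ns_or_mask], ns_q[ns_or_mask],
                np.array([prevalence[t] for t, m in zip(ns_traits, ns_or_mask) if m]))
        ns = pd.DataFrame({
            "snp_id": [f"rs{snp_counter + i:07d}" for i in range(n_ns)],
            "chrom": genes["chrom"].to_numpy()[g_idx],
            "pos": genes["start"].to_numpy()[g_idx] + rng.integers(200, cfg.gene_length, n_ns),
            "locus_id": genes["locus_id"].to_numpy()[g_idx],
            "trait": ns_traits,
            "study_id": [study_pools[t][0] for t in ns_traits],
            "p_value": 10.0 ** (-rng.uniform(4.0, 7.2, size=n_ns)),
            "effect_kind": ns_kind,
            "effect_value": ns_val,
            "risk_allele_freq": ns_q,
        })
        snp_counter += n_ns
        extra_frames.append(ns)

    # noise traits: too few genes / studies to survive the robustness filter
    noise_rows = []
    for t in noise_traits:
        n_g = int(rng.integers(4, 12))
        g_idx = rng.choice(n_genes, size=n_g, replace=False)
        studies = [f"GCSTN{noise_traits.index(t)}{j}" for j in range(int(rng.integers(1, 3)))]
        for k, g in enumerate(g_idx):
            noise_rows.append((
                f"rs{snp_counter:07d}", genes.at[int(g), "chrom"],
                int(genes.at[int(g), "start"]) + int(rng.integers(300, cfg.gene_length)),
                genes.at[int(g), "locus_id"], t, studies[k % len(studies)],
                10.0 ** (-rng.uniform(9.0, 15.0)), "beta",
                rng.normal(0.0, 0.1), float(rng.uniform(0.05, 0.95)),
            ))
            snp_counter += 1
    if noise_rows:
        extra_frames.append(pd.DataFrame(noise_rows, columns=catalog_cols))

    catalog = pd.concat([obs[catalog_cols]] + extra_frames, ignore_index=True)
    catalog = catalog.iloc[rng.permutation(len(catalog))].reset_index(drop=True)

    # stepped tracks: gene segments carry the planted values, baseline fills
    b_rows, rr_rows = [], []
    for label, length in cfg.chrom_lengths:
        sub = truth_loci[truth_loci["chrom"] == label].sort_values("start")
        cursor = 0
        for _, g in sub.iterrows():
            if g["start"] > cursor:
                b_rows.append((label, cursor, int(g["start"]),
                               float(np.clip(rng.normal(cfg.b_background_mean,
                                                        cfg.b_background_sd), 0.0, 1.0))))
                rr_rows.append((label, cursor, int(g["start"]),
                                float(10.0 ** _truncated_normal(rng, cfg.rr_log10_mean,
                                                                cfg.rr_log10_sd, 1)[0])))
            b_rows.append((label, int(g["start"]), int(g["end"]), float(g["b_true"])))
            rr_rows.append((label, int(g["start"]), int(g["end"]), float(g["rr_true"])))
            cursor = int(g["end"])
        if cursor < length:
            b_rows.append((label, cursor, length,
                           float(np.clip(rng.normal(cfg.b_background_mean,
                                                    cfg.b_background_sd), 0.0, 1.0))))
            rr_rows.append((label, cursor, length,
                            float(10.0 ** _truncated_normal(rng, cfg.rr_log10_mean,
                                                            cfg.rr_log10_sd, 1)[0])))
    b_track = pd.DataFrame(b_rows, columns=["chrom", "start", "end", "value"])
    rr_track = pd.DataFrame(rr_rows, columns=["chrom", "start", "end", "value"])

    regions = truth_loci[["chrom", "start", "end", "locus_id", "degree"]].rename(
        columns={"locus_id": "label"})

    truth_params = {
        "config": {**asdict(cfg), "chrom_lengths": [list(c) for c in cfg.chrom_lengths]},
        "traits": traits,
        "noise_traits": noise_traits,
        "or_traits": list(or_traits),
        "prevalence": prevalence,
        "domains": domains,
        "study_pools": study_pools,
        "counts": {
            "n_genes": int(n_genes),
            "n_observations": int(n_obs),
            "n_duplicates": int(dup_mask.sum()),
            "n_nonsignificant": int(n_ns),
            "n_noise_rows": int(len(noise_rows)),
            "n_catalog_rows": int(len(catalog)),
        },
    }
    return {
        "catalog": catalog,
        "genes": genes,
        "b_track": b_track,
        "rr_track": rr_track,
        "regions": regions,
        "prevalence": prevalence,
        "domains": domains,
        "truth_loci": truth_loci,
        "truth_observations": obs.drop(columns="gene_idx"),
        "truth_params": truth_params,
    }


def _write_genetic_map(rr_track: pd.DataFrame, path: Path) -> None:
    lines = ["Chromosome\tPosition(bp)\tRate(cM/Mb)\tMap(cM)"]
    for chrom in sorted(rr_track["chrom"].unique()):
        sub = rr_track[rr_track["chrom"] == chrom].sort_values("start")
        cum = 0.0
        for _, seg in sub.iterrows():
            lines.append(f"{chrom}\t{int(seg['start'])}\t{seg['value']!r}\t{cum!r}")
            cum += seg["value"] * (seg["end"] - seg["start"]) / 1e6
        last = sub.iloc[-1]
        lines.append(f"{chrom}\t{int(last['end'])}\t0.0\t{cum!r}")
    path.write_text("\n".join(lines) + "\n")


def _write_gff3(genes: pd.DataFrame, path: Path) -> None:
    lines = ["##gff-version 3"]
    for _, g in genes.iterrows():
        lines.append("\t".join([
            g["chrom"], "pleiobgs", "gene", str(int(g["start"]) + 1), str(int(g["end"])),
            ".", "+", ".", f"ID={g['locus_id']};Name={g['locus_id']}"]))
    path.write_text("\n".join(lines) + "\n")


#: GWAS-Catalog column order used for the synthetic catalog file
_CATALOG_HEADER = {
    "snp_id": "SNPS", "chrom": "CHR_ID", "pos": "CHR_POS",
    "locus_id": "MAPPED_GENE", "trait": "DISEASE/TRAIT",
    "study_id": "STUDY ACCESSION", "p_value": "P-VALUE",
    "effect_kind": "EFFECT_KIND", "effect_value": "OR or BETA",
    "risk_allele_freq": "RISK ALLELE FREQUENCY",
}


def generate_bundle(cfg: GeneratorConfig, outdir) -> dict:
    """Write a complete synthetic input bundle and its truth files.

    Produces, under ``outdir``: ``catalog.tsv`` (GWAS-Catalog column
    dialect), ``genes.bed`` and ``genes.gff3``, ``b_track.bedgraph``,
    ``genetic_map.txt``, ``regions.tsv``, ``prevalence.yaml``,
    ``domains.tsv``, ``truth_loci.tsv``, ``truth_observations.tsv`` and
    ``truth.json``.  Identical (config, seed) yields byte-identical output.

    Returns a dict with the paths and the in-memory tables.
    """
    tables = generate_tables(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    cat = tables["catalog"].rename(columns=_CATALOG_HEADER)[list(_CATALOG_HEADER.values())]
    paths["catalog"] = outdir / "catalog.tsv"
    cat.to_csv(paths["catalog"], sep="\t", index=False)

    paths["genes_bed"] = outdir / "genes.bed"
    tables["genes"][["chrom", "start", "end", "locus_id"]].to_csv(
        paths["genes_bed"], sep="\t", index=False, header=False)
    paths["genes_gff3"] = outdir / "genes.gff3"
    _write_gff3(tables["genes"], paths["genes_gff3"])

    paths["b_track"] = outdir / "b_track.bedgraph"
    tables["b_track"].to_csv(paths["b_track"], sep="\t", index=False, header=False)
    paths["genetic_map"] = outdir / "genetic_map.txt"
    _write_genetic_map(tables["rr_track"], paths["genetic_map"])

    paths["regions"] = outdir / "regions.tsv"
    tables["regions"].to_csv(paths["regions"], sep="\t", index=False)

    paths["prevalence"] = outdir / "prevalence.yaml"
    with open(paths["prevalence"], "w") as fh:
        yaml.safe_dump(dict(sorted(tables["prevalence"].items())), fh)
    paths["domains"] = outdir / "domains.tsv"
    pd.DataFrame(sorted(tables["domains"].items()), columns=["trait", "domain"]).to_csv(
        paths["domains"], sep="\t", index=False)

    paths["truth_loci"] = outdir / "truth_loci.tsv"
    tables["truth_loci"].to_csv(paths["truth_loci"], sep="\t", index=False)
    paths["truth_observations"] = outdir / "truth_observations.tsv"
    tables["truth_observations"].to_csv(paths["truth_observations"], sep="\t", index=False)
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(tables["truth_params"], sort_keys=True, indent=1) + "\n")

    return {"paths": paths, **tables}


def simulate_region_table(
    seed: int,
    n_regions: int = 200,
    b_intercept: float = 0.75,
    b_degree_slope: float = -0.02,
    b_rr_slope: float = 0.15,
    b_sd: float = 0.03,
    rr_log10_mean: float = 0.0,
    rr_log10_sd: float = 0.4,
    degree_ratio: float = 0.5,
    max_degree: int = 12,
) -> pd.DataFrame:
    """A light-weight annotated region table with planted B/RR/degree law.

    Gaussian residuals around the planted linear model make the OLS t tests
    exact, which is what the null-calibration checks rely on.  Returns the
    columns consumed by :func:`pleiobgs.regress.degree_regressions`.
    """
    rng = np.random.default_rng(seed)
    degree = _truncated_geometric(rng, n_regions, degree_ratio, max_degree)
    log10rr = _truncated_normal(rng, rr_log10_mean, rr_log10_sd, n_regions)
    b = np.clip(
        b_intercept + b_degree_slope * degree + b_rr_slope * log10rr
        + rng.normal(0.0, b_sd, n_regions),
        0.0, 1.0)
    return pd.DataFrame({
        "label": [f"REGION{i:05d}" for i in range(n_regions)],
        "degree": degree.astype(int),
        "B": b,
        "RR": 10.0 ** log10rr,
        "log10RR": log10rr,
        "complete": True,
    })
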