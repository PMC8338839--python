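"""Degree of pleiotropy and per-degree summaries.

A locus associated with 1, 2, 3, ... distinct traits (after trait
clustering) has pleiotropy degree 1 (non-pleiotropic), 2, 3, ...  Effect
sizes are summarised as absolute homozygous effects ``|2 beta|`` -- risk
allele coding makes signs arbitrary across traits -- pooled over trait-locus
observations; MAF is a per-locus quantity; heritability contributions are
per trait-locus pair.

Two dispersion statistics are distinguished deliberately:

* :func:`within_locus_sd` -- the sample SD of the several effects of one
  pleiotropic locus, averaged within a degree class.  Measures how
  *disparate* a locus's effects on its traits are.
* :func:`variance_of_locus_means` -- the variance across loci of each
  locus's mean effect.  This alternative shrinks with degree simply by the
  law of large numbers (more effects averaged per locus), independent of
  any biology, and is reported only for contrast.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "assign_degrees",
    "observation_table",
    "within_locus_sd",
    "variance_of_locus_means",
    "summarize_by_degree",
    "domain_summary",
]


def observation_table(loci: pd.DataFrame) -> pd.DataFrame:
    """Per (locus, trait) observations with the locus degree attached.

    Input must be one row per (locus_id, trait) with ``beta_liability`` and
    ``h2`` already computed.
    """
    obs = loci.copy()
    if "effect_hom" not in obs:
        obs["effect_hom"] = np.abs(2.0 * obs["beta_liability"].to_numpy(dtype=float))
    degree = obs.groupby("locus_id")["trait"].transform("nunique")
    obs["degree"] = degree.astype(int)
    return obs


def assign_degrees(loci: pd.DataFrame) -> pd.DataFrame:
    """One profile row per locus: degree, MAF and representative coordinates.

    The degree is the number of distinct trait labels; the representative
    SNP (chrom/pos/snp_id) is the one with the lowest p-value among the
    locus's trait associations; the locus MAF is the mean of the per-trait
    MAFs (a single planted value per locus in the synthetic bundles).
    """
    obs = observation_table(loci)
    best = obs.sort_values(["p_value", "snp_id"], kind="mergesort").drop_duplicates("locus_id")
    agg = obs.groupby("locus_id").agg(
        degree=("trait", "nunique"),
        maf=("maf", "mean"),
        mean_effect=("effect_hom", "mean"),
        total_h2=("h2", "sum"),
    )
    profiles = best.set_index("locus_id")[["chrom", "pos", "snp_id"]].join(agg)
    return profiles.reset_index().sort_values("locus_id", kind="mergesort").reset_index(drop=True)


def within_locus_sd(effects) -> float:
    """Sample SD (n-1 denominator) of one locus's per-trait effect sizes.

    Undefined (NaN, not zero) for a locus with a single trait.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.size < 2:
        return math.nan
    return float(np.std(effects, ddof=1))


def variance_of_locus_means(obs: pd.DataFrame, degree: int) -> float:
    """Variance across loci of degree ``degree`` of their mean effects.

    Undefined (NaN) with fewer than two loci at that degree.
    """
    sub = obs[obs["degree"] == degree]
    means = sub.groupby("locus_id")["effect_hom"].mean()
    if len(means) < 2:
        return math.nan
    return float(np.var(means.to_numpy(), ddof=1))


def summarize_by_degree(obs: pd.DataFrame) -> pd.DataFrame:
    """Per-degree summary: counts, mean effect, mean within-locus SD, MAF, h2.

    Mean effect and mean h2 pool trait-locus observations; MAF and the
    within-locus SD average per locus (the SD only over loci of degree >= 2).
    """
    per_locus = obs.groupby("locus_id").agg(
        degree=("degree", "first"),
        maf=("maf", "mean"),
        sd=("effect_hom", lambda e: within_locus_sd(e.to_numpy())),
    )
    rows = []
    for degree in sorted(obs["degree"].unique()):
        sub = obs[obs["degree"] == degree]
        locs = per_locus[per_locus["degree"] == degree]
        rows.append({
            "degree": int(degree),
            "n_loci": int(len(locs)),
            "n_observations": int(len(sub)),
            "mean_effect": float(sub["effect_hom"].mean()),
            "mean_within_locus_sd": float(locs["sd"].mean()) if degree >= 2 else math.nan,
            "mean_maf": float(locs["maf"].mean()),
            "mean_h2": float(sub["h2"].mean()),
            "var_of_locus_means": variance_of_locus_means(obs, int(degree)),
        })
    return pd.DataFrame(rows)


def domain_summary(obs: pd.DataFrame, domain_map: Mapping[str, str]) -> pd.DataFrame:
    """Per-domain proportion of pleiotropic loci, averaged over traits.

    For each trait, the fraction of its loci with degree >= 2; for each
    functional domain, the mean of that fraction over its member traits.
    Every trait must be mapped to a domain.
    """
    unmapped = sorted(set(obs["trait"]) - set(domain_map))
    if unmapped:
        raise ConfigurationError("traits missing from the domain map: " + ", ".join(unmapped))
    per_trait = (
        obs.assign(pleio=obs["degree"].ge(2))
        .groupby("trait")["pleio"].mean()
        .rename("prop_pleiotropic")
        .reset_index()
    )
    per_trait["domain"] = per_trait["trait"].map(domain_map)
    out = (per_trait.groupby("domain")
           .agg(n_traits=("trait", "nunique"), prop_pleiotropic=("prop_pleiotropic", "mean"))
           .reset_index()
           .sort_values("domain", kind="mergesort")
           .reset_index(drop=True))
    return out
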