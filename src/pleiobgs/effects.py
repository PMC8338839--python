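"""Liability-scale effect sizes for dichotomous traits.

For a disease trait with population prevalence ``K``, susceptibility is
modelled as a latent standard-normal liability; an individual is affected
when liability exceeds the threshold ``t = Phi^{-1}(1 - K)``.  A biallelic
risk locus with risk-allele frequency ``q`` acts multiplicatively on the
odds of disease: genotype ``i`` (risk-allele count 0, 1, 2) has penetrance
``p_i`` with ``odds(p_i) = odds(p_0) * OR**i``.  Given ``(OR, q, K)`` the
baseline penetrance ``p_0`` is pinned down by the population constraint

    f_0 p_0 + f_1 p_1 + f_2 p_2 = K,

where ``(f_0, f_1, f_2) = ((1-q)^2, 2q(1-q), q^2)`` are Hardy-Weinberg
genotype frequencies.  Each genotype's mean liability is then recovered as
``mu_i = t - Phi^{-1}(1 - p_i)`` (unit within-genotype variance), and the
per-allele effect ``beta`` is the frequency-weighted least-squares slope of
``mu_i`` on allele count -- the allele-substitution effect.  Quantitative
traits report ``beta`` directly in trait-SD units and bypass all of this.

The contribution of a locus to heritability is ``h2 = 2 beta^2 q (1 - q)``.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtri

from .errors import ConfigurationError, NumericalError

__all__ = [
    "liability_threshold",
    "solve_penetrances",
    "liability_effect",
    "liability_effect_array",
    "heritability_contribution",
    "convert_effects",
]

#: residual tolerance on the population-prevalence constraint
PENETRANCE_TOL = 1e-12


def liability_threshold(K: float) -> float:
    """Liability threshold ``t`` with ``Phi(t) = 1 - K``.

    Parameters
    ----------
    K : population prevalence, in the open interval (0, 1).
    """
    if not 0.0 < K < 1.0:
        raise NumericalError(f"prevalence K must lie in (0,1), got {K!r}")
    # Phi^{-1}(1-K) == -Phi^{-1}(K), evaluated in the precise branch
    return -float(ndtri(K))


def _hw_freqs(q):
    return (1.0 - q) ** 2, 2.0 * q * (1.0 - q), q ** 2


def _prevalence_gap(u, log_or, q, K):
    """Population prevalence minus K as a function of u = log odds(p0)."""
    f0, f1, f2 = _hw_freqs(q)
    x0 = np.exp(u)
    x1 = np.exp(u + log_or)
    x2 = np.exp(u + 2.0 * log_or)
    p0 = x0 / (1.0 + x0)
    p1 = x1 / (1.0 + x1)
    p2 = x2 / (1.0 + x2)
    return f0 * p0 + f1 * p1 + f2 * p2 - K, (p0, p1, p2)


def solve_penetrances(OR: float, q: float, K: float) -> tuple[float, float, float]:
    """Genotype penetrances ``(p0, p1, p2)`` under a multiplicative odds model.

    Solves the monotone 1-D problem in ``log odds(p0)``: the population
    prevalence is strictly increasing in the baseline odds, and the root is
    bracketed by ``log odds(K) -/+ 2|log OR|``.
    """
    if OR <= 0.0:
        raise NumericalError(f"odds ratio must be positive, got {OR!r}")
    if not 0.0 < q < 1.0:
        raise NumericalError(f"frequency q must lie in (0,1), got {q!r}")
    if not 0.0 < K < 1.0:
        raise NumericalError(f"prevalence K must lie in (0,1), got {K!r}")
    if OR == 1.0:
        return (K, K, K)
    log_or = float(np.log(OR))
    k0 = float(np.log(K) - np.log1p(-K))
    span = 2.0 * abs(log_or) + 1e-9
    try:
        root = brentq(
            lambda u: _prevalence_gap(u, log_or, q, K)[0],
            k0 - span,
            k0 + span,
            xtol=1e-13,
            rtol=8.9e-16,
            maxiter=200,
        )
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
        raise NumericalError(f"penetrance solve failed for OR={OR}, q={q}, K={K}: {exc}")
    gap, ps = _prevalence_gap(root, log_or, q, K)
    if abs(gap) > PENETRANCE_TOL:
        raise NumericalError(
            f"penetrance solve residual {abs(gap):.3e} exceeds {PENETRANCE_TOL} "
            f"for OR={OR}, q={q}, K={K}"
        )
    return tuple(float(p) for p in ps)


def _allelic_slope(p0, p1, p2, q, K):
    """Weighted LS slope of genotype liability means on allele count."""
    t = -ndtri(K)
    mu = np.stack([t + ndtri(p0), t + ndtri(p1), t + ndtri(p2)])
    f = np.stack(_hw_freqs(q))
    i = np.array([0.0, 1.0, 2.0]).reshape(3, *([1] * (mu.ndim - 1)))
    ibar = (f * i).sum(axis=0)  # = 2q under HWE
    mubar = (f * mu).sum(axis=0)
    num = (f * (i - ibar) * (mu - mubar)).sum(axis=0)
    den = (f * (i - ibar) ** 2).sum(axis=0)
    return num / den


def liability_effect(OR: float, q: float, K: float) -> float:
    """Per-allele liability effect ``beta`` implied by ``(OR, q, K)``.

    ``beta`` has the sign of ``log OR`` and is exactly zero at ``OR = 1``.
    """
    if OR == 1.0:
        # the no-effect case is exact by construction; avoid rounding noise
        if not 0.0 < q < 1.0:
            raise NumericalError(f"frequency q must lie in (0,1), got {q!r}")
        if not 0.0 < K < 1.0:
            raise NumericalError(f"prevalence K must lie in (0,1), got {K!r}")
        return 0.0
    p0, p1, p2 = solve_penetrances(OR, q, K)
    return float(_allelic_slope(np.float64(p0), np.float64(p1), np.float64(p2), q, K))


def _penetrances_bisect(log_or, q, K, iters=80):
    """Vectorised bisection for the penetrance solve (arrays broadcast)."""
    log_or = np.asarray(log_or, dtype=float)
    q = np.asarray(q, dtype=float)
    K = np.asarray(K, dtype=float)
    k0 = np.log(K) - np.log1p(-K)
    span = 2.0 * np.abs(log_or) + 1e-9
    lo = k0 - span
    hi = k0 + span
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        gap, _ = _prevalence_gap(mid, log_or, q, K)
        hi = np.where(gap > 0.0, mid, hi)
        lo = np.where(gap > 0.0, lo, mid)
    _, ps = _prevalence_gap(0.5 * (lo + hi), log_or, q, K)
    return ps


def liability_effect_array(OR, q, K):
    """Vectorised :func:`liability_effect` over broadcastable arrays."""
    OR = np.asarray(OR, dtype=float)
    q = np.asarray(q, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any(OR <= 0.0):
        raise NumericalError("odds ratios must be positive")
    if np.any((q <= 0.0) | (q >= 1.0)) or np.any((K <= 0.0) | (K >= 1.0)):
        raise NumericalError("q and K must lie in (0,1)")
    log_or = np.log(OR)
    p0, p1, p2 = _penetrances_bisect(log_or, q, K)
    beta = _allelic_slope(p0, p1, p2, q, K)
    return np.where(log_or == 0.0, 0.0, beta)


def heritability_contribution(beta, q):
    """Locus heritability contribution ``h2 = 2 beta^2 q (1 - q)``.

    Symmetric under ``beta -> -beta`` and under allele relabelling
    ``q -> 1 - q``.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0.0) | (q >= 1.0)):
        raise NumericalError("q must lie in (0,1)")
    beta = np.asarray(beta, dtype=float)
    out = 2.0 * beta * beta * (q * (1.0 - q))
    return float(out) if out.ndim == 0 else out


def convert_effects(loci: pd.DataFrame, prevalence: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Attach liability-scale effects and heritability contributions to loci.

    Rows whose ``effect_kind`` is ``"beta"`` carry their reported effect
    through unchanged (trait-SD units).  Rows reported as odds ratios are
    converted through the threshold model, which requires the trait's
    prevalence ``K`` in ``prevalence``; a missing entry is a configuration
    error.  Rows with no ``effect_kind`` are inferred: odds ratio if the
    trait appears in the prevalence map, beta otherwise.

    Returns a copy with ``beta_liability``, ``effect_hom`` (absolute
    homozygous effect ``|2 beta|``) and ``h2`` columns added.
    """
    prevalence = dict(prevalence or {})
    out = loci.copy()
    kind = out.get("effect_kind")
    if kind is None:
        kind = pd.Series(pd.NA, index=out.index)
    kind = kind.where(kind.notna(), out["trait"].map(
        lambda t: "odds_ratio" if t in prevalence else "beta"))
    is_or = (kind == "odds_ratio").to_numpy()

    beta = out["effect_value"].to_numpy(dtype=float).copy()
    if is_or.any():
        traits = out.loc[is_or, "trait"]
        missing = sorted(set(traits) - set(prevalence))
        if missing:
            raise ConfigurationError(
                "no prevalence configured for odds-ratio trait(s): " + ", ".join(missing))
        Ks = traits.map(prevalence).to_numpy(dtype=float)
        beta[is_or] = liability_effect_array(
            out.loc[is_or, "effect_value"].to_numpy(dtype=float),
            out.loc[is_or, "risk_allele_freq"].to_numpy(dtype=float),
            Ks,
        )
    out["effect_kind"] = kind
    out["beta_liability"] = beta
    out["effect_hom"] = np.abs(2.0 * beta)
    out["h2"] = heritability_contribution(beta, out["risk_allele_freq"].to_numpy(dtype=float))
    return out
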