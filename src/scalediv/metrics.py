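"""Biodiversity metrics at the subplot (α) and pooled site (γ) scales.

Implements the individual-based metric family used for two-scale diversity
partitioning:

* ``N`` — total abundance and ``S`` — observed richness;
* ``S_n`` — rarefied richness, the expected species count in a random
  subsample of *n* individuals,
  ``E[S_n] = Σ_i [1 − C(N−N_i, n) / C(N, n)]``,
  evaluated in log-gamma space so it is stable for read totals up to ≥ 1e7;
* ``PIE`` — probability of interspecific encounter with Hurlbert's
  without-replacement correction, ``(N/(N−1))·(1 − Σ (N_i/N)²)``;
* ``S_PIE = 1/(1 − PIE)`` — PIE as an effective (Hill-like) species number;
* multiplicative β-diversity, γ-value / mean α-value, with β-S_n computed
  from the *same* n at both scales so it isolates spatial aggregation from
  density and SAD shape.

The rarefaction base n is the minimum subplot total across both management
types of a site; γ-scale rarefaction uses n × (number of subplots in the
group) so both scales sample the same per-subplot effort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .data_model import CommunityTable, StratumError, pool_group

logger = logging.getLogger("scalediv")

ALPHA_METRICS = ("N", "S", "S_n", "S_PIE")
BETA_METRICS = ("beta_S", "beta_S_n", "beta_S_PIE")


@dataclass(frozen=True)
class MetricSet:
    """Per-group diversity metrics at one scale.

    At the α-scale the values are arithmetic means across subplots; at the
    γ-scale they are computed on the pooled abundance vector.
    """

    scale: str           # "alpha" | "gamma"
    site: str
    management: str
    n_base: int          # subplot-level rarefaction base n
    N: float
    S: float
    S_n: float
    PIE: float
    S_PIE: float
    n_subplots: int


@dataclass(frozen=True)
class BetaSet:
    """Multiplicative β-diversity (γ / mean α) per group."""

    site: str
    management: str
    n_base: int
    beta_S: float
    beta_S_n: float
    beta_S_PIE: float


# ---------------------------------------------------------------------------
# core metric kernels (vectorised; rows = communities)
# ---------------------------------------------------------------------------


def rarefied_richness_matrix(counts: np.ndarray, n) -> np.ndarray:
    """E[S_n] for each row of a communities × taxa count matrix.

    ``n`` may be a scalar or a per-row vector.  Rows with total < n yield
    NaN.  Uses log-gamma binomial ratios:
    ``C(N−N_i, n)/C(N, n) = exp(lnΓ(N−N_i+1) + lnΓ(N−n+1)
    − lnΓ(N−N_i−n+1) − lnΓ(N+1))``.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    totals = counts.sum(axis=1)
    n = np.broadcast_to(np.asarray(n, dtype=float), totals.shape)

    with np.errstate(invalid="ignore"):
        rest = totals[:, None] - counts  # N − N_i
        log_ratio = (
            gammaln(rest + 1.0)
            + gammaln(totals - n + 1.0)[:, None]
            - gammaln(rest - n[:, None] + 1.0)
            - gammaln(totals + 1.0)[:, None]
        )
    prob_absent = np.where(rest >= n[:, None], np.exp(log_ratio), 0.0)
    # species with zero count contribute nothing
    contrib = np.where(counts > 0, 1.0 - prob_absent, 0.0)
    out = contrib.sum(axis=1)
    out[(n < 1) | (n > totals)] = np.nan
    return out


def pie_matrix(counts: np.ndarray) -> np.ndarray:
    """Hurlbert's PIE for each row; NaN where the row total is < 2."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    totals = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p2 = (counts / totals[:, None]) ** 2
        pie = totals / (totals - 1.0) * (1.0 - np.nansum(p2, axis=1))
    pie[totals < 2] = np.nan
    # guard tiny negatives from cancellation in monocultures
    return np.where(np.abs(pie) < 1e-15, 0.0, pie)


def s_pie_matrix(counts: np.ndarray) -> np.ndarray:
    """Effective species number 1/(1−PIE) per row; inf→NaN with a warning."""
    pie = pie_matrix(counts)
    with np.errstate(divide="ignore"):
        s_pie = 1.0 / (1.0 - pie)
    degenerate = np.isinf(s_pie)
    if degenerate.any():
        logger.warning("PIE = 1 in %d communities; S_PIE reported as missing",
                       int(degenerate.sum()))
        s_pie = np.where(degenerate, np.nan, s_pie)
    return s_pie


# ---------------------------------------------------------------------------
# scalar wrappers (the documented single-community interface)
# ---------------------------------------------------------------------------


def rarefied_richness(counts, n: int) -> float:
    """Expected species count in a random subsample of ``n`` individuals."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if n < 1:
        raise ValueError("rarefaction level n must be >= 1")
    if n > total:
        raise ValueError(f"rarefaction level n={n} exceeds total N={total:g}")
    return float(rarefied_richness_matrix(counts[None, :], n)[0])


def hurlbert_pie(counts) -> float:
    """Probability that two individuals drawn without replacement differ in
    species; NaN when fewer than two individuals are present."""
    return float(pie_matrix(np.asarray(counts, dtype=float)[None, :])[0])


def effective_species_pie(counts) -> float:
    """PIE expressed as an effective number of equally common species."""
    return float(s_pie_matrix(np.asarray(counts, dtype=float)[None, :])[0])


# ---------------------------------------------------------------------------
# scale-level assembly
# ---------------------------------------------------------------------------


def rarefaction_base_n(table: CommunityTable, site: str) -> int:
    """Minimum subplot total N at a site, across both management types.

    Subplots with fewer than 2 individuals cannot support PIE or a
    meaningful rarefaction level; they are excluded here with a warning.
    """
    mask = np.array([s.site == site for s in table.samples], dtype=bool)
    if not mask.any():
        raise StratumError(f"no samples for site {site!r}")
    totals = table.abundance[mask].sum(axis=1)
    tiny = totals < 2
    if tiny.any():
        ids = [s.sample_id for s, m in zip(table.samples, mask) if m]
        bad = [i for i, t in zip(ids, tiny) if t]
        logger.warning("site %s: excluding %d subplot(s) with N < 2 from "
                       "base-n determination: %s", site, len(bad), bad[:5])
    totals = totals[~tiny]
    if totals.size == 0:
        raise StratumError(f"site {site!r} has no subplot with N >= 2")
    return int(totals.min())


def subplot_metric_frame(counts: np.ndarray, n: int) -> dict[str, np.ndarray]:
    """Per-subplot N, S, S_n(n), PIE, S_PIE for a subplot × taxon matrix."""
    counts = np.atleast_2d(counts)
    return {
        "N": counts.sum(axis=1),
        "S": (counts > 0).sum(axis=1).astype(float),
        "S_n": rarefied_richness_matrix(counts, n),
        "PIE": pie_matrix(counts),
        "S_PIE": s_pie_matrix(counts),
    }


def alpha_metrics(
    table: CommunityTable, site: str, management: str, n: int
) -> tuple[MetricSet, dict[str, np.ndarray]]:
    """α-scale metrics: per-subplot values plus their arithmetic means.

    Subplots where a metric is undefined (N < n for S_n, N < 2 for PIE)
    carry NaN and are dropped from the mean for that metric only.
    """
    mask = table.group_mask(site, management)
    if not mask.any():
        raise StratumError(f"no samples for site={site!r}, management={management!r}")
    per = subplot_metric_frame(table.abundance[mask], n)
    ms = MetricSet(
        scale="alpha", site=site, management=management, n_base=int(n),
        N=float(np.nanmean(per["N"])),
        S=float(np.nanmean(per["S"])),
        S_n=float(np.nanmean(per["S_n"])),
        PIE=float(np.nanmean(per["PIE"])),
        S_PIE=float(np.nanmean(per["S_PIE"])),
        n_subplots=int(mask.sum()),
    )
    return ms, per


def gamma_metrics(
    table: CommunityTable, site: str, management: str, n: int
) -> MetricSet:
    """γ-scale metrics on the pooled group vector.

    Pooled richness is rarefied at ``n × n_subplots`` so the γ-scale target
    matches the summed per-subplot effort of the α-scale.
    """
    pooled = pool_group(table, site, management)
    k = int(table.group_mask(site, management).sum())
    return MetricSet(
        scale="gamma", site=site, management=management, n_base=int(n),
        N=float(pooled.sum()),
        S=float((pooled > 0).sum()),
        S_n=rarefied_richness(pooled, n * k),
        PIE=hurlbert_pie(pooled),
        S_PIE=effective_species_pie(pooled),
        n_subplots=k,
    )


def beta_partition(
    alpha: tuple[MetricSet, dict[str, np.ndarray]],
    gamma_pooled: np.ndarray,
    n: int,
) -> BetaSet:
    """Multiplicative β-diversity γ/ᾱ for S, S_n and S_PIE.

    β-S_n rarefies the pooled vector at the *same* n used per subplot
    (not n × subplots), which is what makes it sensitive to intraspecific
    spatial aggregation while controlling for N and SAD shape.
    """
    ms, per = alpha
    mean_s = float(np.nanmean(per["S"]))
    mean_sn = float(np.nanmean(per["S_n"]))
    mean_spie = float(np.nanmean(per["S_PIE"]))
    if not all(m > 0 for m in (mean_s, mean_sn, mean_spie) if np.isfinite(m)):
        raise ValueError("zero mean α-scale value; β undefined")
    gamma_s = float((gamma_pooled > 0).sum())
    gamma_sn = rarefied_richness(gamma_pooled, n)
    gamma_spie = effective_species_pie(gamma_pooled)
    return BetaSet(
        site=ms.site, management=ms.management, n_base=int(n),
        beta_S=gamma_s / mean_s,
        beta_S_n=gamma_sn / mean_sn,
        beta_S_PIE=gamma_spie / mean_spie,
    )


def group_metrics(
    table: CommunityTable, site: str, management: str, n: int
) -> tuple[MetricSet, MetricSet, BetaSet, dict[str, np.ndarray]]:
    """Convenience bundle: (α MetricSet, γ MetricSet, BetaSet, per-subplot)."""
    alpha = alpha_metrics(table, site, management, n)
    gamma = gamma_metrics(table, site, management, n)
    pooled = pool_group(table, site, management)
    beta = beta_partition(alpha, pooled, n)
    return alpha[0], gamma, beta, alpha[1]
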