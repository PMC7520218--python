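"""Treatment-effect inference across spatial scales.

Effect sizes are log-response ratios ln(pasture/meadow), meadow as
reference.  At the α-scale (subplot values, replicated within groups) the
test is a one-way ANOVA F.  At the γ-scale there is a single value per
group, so significance comes from a permutation null: subplots are randomly
reassigned to the two management labels (group sizes preserved), the pooled
γ metrics recomputed, and the two-sided p-value uses the add-one rule
``p = (1 + #{|LRR*| ≥ |LRR_obs|}) / (n_perm + 1)``.  β-diversity metrics are
tested the same way.

Unbalanced designs (unequal plot counts per management) are standardized by
enumerating every subset of the larger group's plots of the smaller group's
size; each subset defines one balanced replicate dataset.  Replicate LRRs
are averaged arithmetically and replicate p-values combined with the
(unweighted) harmonic mean.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .data_model import CommunityTable, StratumError
from .metrics import (
    ALPHA_METRICS,
    alpha_metrics,
    beta_partition,
    gamma_metrics,
    pie_matrix,
    pool_group,
    rarefaction_base_n,
    rarefied_richness_matrix,
    s_pie_matrix,
    subplot_metric_frame,
)

logger = logging.getLogger("scalediv")

GAMMA_TEST_METRICS = ("N", "S", "S_n", "S_PIE")
BETA_TEST_METRICS = ("beta_S_n", "beta_S_PIE")

_MAX_RESAMPLE_ROUNDS = 100


@dataclass(frozen=True)
class EffectTest:
    """One metric × one scale × one site: effect size and test."""

    site: str
    taxon_group: str
    metric: str
    scale: str            # "alpha" | "gamma" | "beta"
    lrr: float            # ln(pasture/meadow)
    statistic: float      # F (alpha) or observed LRR (gamma/beta)
    p_value: float
    n_perm: int
    method: str           # "anova" | "permutation"


@dataclass(frozen=True)
class StandardizationPlan:
    """Balanced-replicate plan for an unbalanced (site, management) design."""

    site: str
    larger_group: str
    smaller_group: str
    plot_combinations: tuple[tuple[str, ...], ...]
    cap: int
    seed: int | None
    balanced: bool

    @property
    def n_replicates(self) -> int:
        return len(self.plot_combinations)


@dataclass
class CombinedResult:
    """Replicate effects for one metric×scale, averaged across the plan."""

    metric: str
    scale: str
    replicates: list[EffectTest]
    lrr: float = float("nan")          # arithmetic mean of replicate LRRs
    p_value: float = float("nan")      # harmonic mean of replicate p-values

    def __post_init__(self) -> None:
        lrrs = [r.lrr for r in self.replicates if np.isfinite(r.lrr)]
        ps = [r.p_value for r in self.replicates if np.isfinite(r.p_value)]
        dropped = len(self.replicates) - len(lrrs)
        if dropped:
            logger.info("combined %s/%s: dropped %d replicate(s) with missing LRR",
                        self.metric, self.scale, dropped)
        if lrrs:
            self.lrr = float(np.mean(lrrs))
        if ps:
            self.p_value = combine_pvalues_harmonic(ps)


@dataclass(frozen=True)
class Classification:
    """Scale-dependence category of one metric's α vs γ response."""

    metric: str
    category: str          # qualitative_reversal | alpha_only | gamma_only |
                           # consistent_both | none | undetermined
    lrr_alpha: float
    lrr_gamma: float
    p_alpha: float
    p_gamma: float
    on_identity_line: bool


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for a per-site, per-taxon analysis run."""

    n_perm: int = 199
    alpha_level: float = 0.05
    standardization_cap: int = 200
    seed: int | None = None
    statistic: str = "lrr"            # "lrr" | "diff" permutation statistic
    permutation_unit: str = "subplot"  # "subplot" | "plot"
    alpha_n_perm: int = 0              # >0: permutation p for the α-scale F


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------


def log_response_ratio(x_pasture: float, x_meadow: float) -> float:
    """ln(pasture) − ln(meadow); positive means higher under pasture."""
    if not (x_pasture > 0 and x_meadow > 0) or not (
        np.isfinite(x_pasture) and np.isfinite(x_meadow)
    ):
        logger.warning("non-positive or missing value in LRR (%s, %s)",
                       x_pasture, x_meadow)
        return float("nan")
    return math.log(x_pasture) - math.log(x_meadow)


def combine_pvalues_harmonic(ps: Sequence[float]) -> float:
    """Unweighted harmonic mean of p-values: k / Σ(1/p_i)."""
    ps = np.asarray(list(ps), dtype=float)
    if ps.size == 0:
        raise ValueError("cannot combine an empty list of p-values")
    if np.any(ps <= 0) or np.any(ps > 1) or not np.all(np.isfinite(ps)):
        raise ValueError("p-values must lie in (0, 1]")
    return float(ps.size / np.sum(1.0 / ps))


def _anova_f(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-group one-way ANOVA F and its p from F(1, n−2).

    Degenerate cases: no within-group variance and equal means → F = 0,
    p = 1; no within-group variance and unequal means → F = ∞, p = tiny.
    """
    n = a.size + b.size
    grand = (a.sum() + b.sum()) / n
    ss_between = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df1, df2 = 1, n - 2
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), float(np.finfo(float).tiny)
    f = (ss_between / df1) / (ss_within / df2)
    p = float(scipy.stats.f.sf(f, df1, df2))
    return float(f), max(p, float(np.finfo(float).tiny))


def alpha_scale_test(
    values_pasture: Sequence[float],
    values_meadow: Sequence[float],
    site: str = "",
    taxon_group: str = "",
    metric: str = "",
    n_perm: int = 0,
    rng: np.random.Generator | None = None,
) -> EffectTest:
    """One-way ANOVA on subplot-level metric values (pasture vs meadow).

    The LRR is computed from the group means.  With ``n_perm > 0`` the
    F-statistic's p-value is instead taken from label permutations
    (add-one rule), as an exchangeability-based alternative to the F
    distribution.
    """
    a = np.asarray(values_pasture, dtype=float)
    b = np.asarray(values_meadow, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return EffectTest(site, taxon_group, metric, "alpha",
                          float("nan"), float("nan"), float("nan"), 0, "anova")
    f, p = _anova_f(a, b)
    method = "anova"
    if n_perm > 0:
        rng = np.random.default_rng() if rng is None else rng
        pooled = np.concatenate([a, b])
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            f_null, _ = _anova_f(perm[: a.size], perm[a.size:])
            if f_null >= f - 1e-12:
                hits += 1
        p = (1 + hits) / (n_perm + 1)
        method = "anova_permutation"
    lrr = log_response_ratio(float(a.mean()), float(b.mean()))
    return EffectTest(site, taxon_group, metric, "alpha", lrr, f, p,
                      n_perm if method != "anova" else 0, method)


# ---------------------------------------------------------------------------
# γ/β permutation engine (vectorised over permutations)
# ---------------------------------------------------------------------------


def _nanmean_by_assignment(values: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Mean of per-subplot ``values`` over each row's selected subplots,
    ignoring NaNs.  ``member``: draws × subplots boolean matrix."""
    finite = np.isfinite(values)
    v = np.where(finite, values, 0.0)
    num = member @ v
    den = member @ finite.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _group_statistics(
    member_p: np.ndarray,
    counts: np.ndarray,
    n_base: int,
    sub_sn: np.ndarray,
    sub_spie: np.ndarray,
    metrics: Sequence[str],
) -> dict[str, np.ndarray]:
    """Per-draw values of each metric's (pasture_value, meadow_value) pair,
    returned as draws × 2 arrays.

    ``member_p``: draws × subplots boolean pasture membership, identical
    group size in every row.
    """
    member_p = member_p.astype(float)
    member_m = 1.0 - member_p
    m_p = int(member_p[0].sum())
    m_m = member_p.shape[1] - m_p
    pooled_p = member_p @ counts
    pooled_m = member_m @ counts

    out: dict[str, np.ndarray] = {}
    if "N" in metrics:
        out["N"] = np.stack([pooled_p.sum(1), pooled_m.sum(1)], axis=1)
    if "S" in metrics:
        out["S"] = np.stack(
            [(pooled_p > 0).sum(1).astype(float), (pooled_m > 0).sum(1).astype(float)],
            axis=1,
        )
    if "S_n" in metrics:
        out["S_n"] = np.stack(
            [
                rarefied_richness_matrix(pooled_p, n_base * m_p),
                rarefied_richness_matrix(pooled_m, n_base * m_m),
            ],
            axis=1,
        )
    if "S_PIE" in metrics:
        out["S_PIE"] = np.stack(
            [s_pie_matrix(pooled_p), s_pie_matrix(pooled_m)], axis=1
        )
    if "beta_S_n" in metrics:
        out["beta_S_n"] = np.stack(
            [
                rarefied_richness_matrix(pooled_p, n_base)
                / _nanmean_by_assignment(sub_sn, member_p),
                rarefied_richness_matrix(pooled_m, n_base)
                / _nanmean_by_assignment(sub_sn, member_m),
            ],
            axis=1,
        )
    if "beta_S_PIE" in metrics:
        out["beta_S_PIE"] = np.stack(
            [
                s_pie_matrix(pooled_p) / _nanmean_by_assignment(sub_spie, member_p),
                s_pie_matrix(pooled_m) / _nanmean_by_assignment(sub_spie, member_m),
            ],
            axis=1,
        )
    return out


def _pair_statistic(pair: np.ndarray, statistic: str) -> np.ndarray:
    """Collapse draws × 2 group values to the permutation statistic."""
    if statistic == "diff":
        return pair[:, 0] - pair[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        lrr = np.log(pair[:, 0]) - np.log(pair[:, 1])
    lrr[(pair <= 0).any(axis=1)] = np.nan
    return lrr


def _draw_assignments(
    rng: np.random.Generator,
    n_draws: int,
    n_units: int,
    k_pasture: int,
    unit_of_sample: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean draws × subplots pasture-membership matrix.

    With ``unit_of_sample`` given (plot index per subplot), whole units are
    reassigned; ``n_units``/``k_pasture`` then refer to plots.
    """
    r = rng.random((n_draws, n_units))
    ranks = np.argsort(r, axis=1)[:, :k_pasture]
    member_units = np.zeros((n_draws, n_units), dtype=bool)
    np.put_along_axis(member_units, ranks, True, axis=1)
    if unit_of_sample is None:
        return member_units
    return member_units[:, unit_of_sample]


def site_permutation_tests(
    table: CommunityTable,
    site: str,
    taxon_group: str = "",
    n_perm: int = 199,
    rng: np.random.Generator | int | None = None,
    metrics: Sequence[str] = GAMMA_TEST_METRICS + BETA_TEST_METRICS,
    statistic: str = "lrr",
    unit: str = "subplot",
    n_base: int | None = None,
) -> dict[str, EffectTest]:
    """Permutation tests for all γ-scale and β metrics of one site at once.

    All metrics share one set of label permutations (the null reassignment
    of subplots — or whole plots with ``unit='plot'`` — to management
    types).  Draws where any requested metric is undefined are redrawn, up
    to a hard cap.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mask_p = table.group_mask(site, "pasture")
    mask_m = table.group_mask(site, "meadow")
    if not mask_p.any() or not mask_m.any():
        raise StratumError(f"site {site!r} lacks one of the management types")
    keep = mask_p | mask_m
    sub = table.select(keep)
    counts = sub.abundance
    is_pasture = np.array([s.management == "pasture" for s in sub.samples])
    if n_base is None:
        n_base = rarefaction_base_n(sub, site)

    per = subplot_metric_frame(counts, n_base)
    sub_sn, sub_spie = per["S_n"], per["S_PIE"]

    if unit == "plot":
        plots = [s.plot for s in sub.samples]
        uniq = list(dict.fromkeys(plots))
        unit_of_sample = np.array([uniq.index(p) for p in plots])
        pasture_plots = {p for p, ip in zip(plots, is_pasture) if ip}
        n_units, k = len(uniq), len(pasture_plots)
    else:
        unit_of_sample = None
        n_units, k = counts.shape[0], int(is_pasture.sum())

    observed_pairs = _group_statistics(
        is_pasture[None, :], counts, n_base, sub_sn, sub_spie, metrics
    )

    member = _draw_assignments(rng, n_perm, n_units, k, unit_of_sample)
    null_pairs = _group_statistics(member, counts, n_base, sub_sn, sub_spie, metrics)
    null_stats = {m: _pair_statistic(null_pairs[m], statistic) for m in metrics}

    # resample draws with any undefined metric (rare: degenerate groups)
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = np.zeros(n_perm, dtype=bool)
        for m in metrics:
            bad |= ~np.isfinite(null_stats[m])
        if not bad.any():
            break
        redraw = _draw_assignments(rng, int(bad.sum()), n_units, k, unit_of_sample)
        pairs = _group_statistics(redraw, counts, n_base, sub_sn, sub_spie, metrics)
        for m in metrics:
            null_stats[m][bad] = _pair_statistic(pairs[m], statistic)
    else:
        raise RuntimeError("could not complete permutation null: persistent "
                           "degenerate draws")

    results: dict[str, EffectTest] = {}
    for m in metrics:
        obs = float(_pair_statistic(observed_pairs[m], statistic)[0])
        pair = observed_pairs[m][0]
        lrr = log_response_ratio(float(pair[0]), float(pair[1]))
        if not np.isfinite(obs):
            p = float("nan")
        else:
            hits = int(np.sum(np.abs(null_stats[m]) >= abs(obs) - 1e-12))
            p = (1 + hits) / (n_perm + 1)
        scale = "beta" if m.startswith("beta") else "gamma"
        results[m] = EffectTest(site, taxon_group, m, scale, lrr, obs, p,
                                n_perm, "permutation")
    return results


def gamma_scale_permutation_test(
    table: CommunityTable,
    site: str,
    metric: str = "S_n",
    n_perm: int = 199,
    seed: int | None = None,
    **kwargs,
) -> EffectTest:
    """Permutation test for a single γ-scale (or β) metric."""
    return site_permutation_tests(
        table, site, n_perm=n_perm, rng=seed, metrics=(metric,), **kwargs
    )[metric]


# ---------------------------------------------------------------------------
# design standardization
# ---------------------------------------------------------------------------


def build_standardization_plan(
    table: CommunityTable,
    site: str,
    cap: int = 200,
    seed: int | None = None,
) -> StandardizationPlan:
    """Enumerate balanced plot subsets of the larger management group.

    With P_large plots against P_small, every C(P_large, P_small) subset
    defines one replicate; above ``cap`` a seeded uniform sample of distinct
    subsets is used.  Balanced designs yield a single identity replicate.
    """
    plots: dict[str, list[str]] = {"pasture": [], "meadow": []}
    for s in table.samples:
        if s.site == site and s.plot not in plots[s.management]:
            plots[s.management].append(s.plot)
    if not plots["pasture"] or not plots["meadow"]:
        raise StratumError(f"site {site!r} lacks one of the management types")

    if len(plots["pasture"]) >= len(plots["meadow"]):
        larger, smaller = "pasture", "meadow"
    else:
        larger, smaller = "meadow", "pasture"
    k = len(plots[smaller])
    if len(plots[larger]) == k:
        return StandardizationPlan(site, larger, smaller,
                                   (tuple(plots[larger]),), cap, seed, True)
    combos = list(itertools.combinations(plots[larger], k))
    if len(combos) > cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(combos), size=cap, replace=False)
        combos = [combos[i] for i in sorted(idx)]
    return StandardizationPlan(site, larger, smaller, tuple(combos), cap, seed, False)


def replicate_table(
    table: CommunityTable, plan: StandardizationPlan, combo: tuple[str, ...]
) -> CommunityTable:
    """Balanced replicate: the smaller group in full plus the chosen plots."""
    chosen = set(combo)
    mask = np.array(
        [
            s.site == plan.site
            and (s.management == plan.smaller_group or s.plot in chosen)
            for s in table.samples
        ],
        dtype=bool,
    )
    return table.select(mask)


# ---------------------------------------------------------------------------
# classification and the per-site driver
# ---------------------------------------------------------------------------


def classify_scale_dependence(
    effect_alpha: EffectTest | CombinedResult,
    effect_gamma: EffectTest | CombinedResult,
    alpha_level: float = 0.05,
) -> Classification:
    """Categorise the α- vs γ-scale response pattern of one metric.

    ``qualitative_reversal``: significant at both scales with opposite LRR
    signs; ``consistent_both``: significant at both with the same sign;
    ``alpha_only`` / ``gamma_only``: significant at one scale; ``none``:
    neither.  Missing effects give ``undetermined``.
    """
    metric = getattr(effect_alpha, "metric", "")
    la, lg = effect_alpha.lrr, effect_gamma.lrr
    pa, pg = effect_alpha.p_value, effect_gamma.p_value
    vals = [la, lg, pa, pg]
    if any(not np.isfinite(v) for v in vals):
        return Classification(metric, "undetermined", la, lg, pa, pg, False)
    sig_a, sig_g = pa < alpha_level, pg < alpha_level
    if sig_a and sig_g:
        category = "qualitative_reversal" if la * lg < 0 else "consistent_both"
    elif sig_a:
        category = "alpha_only"
    elif sig_g:
        category = "gamma_only"
    else:
        category = "none"
    return Classification(metric, category, la, lg, pa, pg,
                          on_identity_line=abs(la - lg) <= 1e-12)


@dataclass
class SiteTaxonResult:
    """Everything inferred for one site × taxonomic group."""

    site: str
    taxon_group: str
    plan: StandardizationPlan
    combined: dict[tuple[str, str], CombinedResult]   # (metric, scale) → result
    classifications: dict[str, Classification]        # metric → category


def run_site_taxon_analysis(
    table: CommunityTable,
    site: str,
    taxon_group: str = "",
    config: AnalysisConfig = AnalysisConfig(),
) -> SiteTaxonResult:
    """Full inference for one site: standardize, test at both scales, classify.

    For every balanced replicate of the standardization plan the α-scale
    ANOVA (N, S, S_n, S_PIE), γ-scale permutation tests and β permutation
    tests (β-S_n, β-S_PIE) are run; replicate LRRs are mean-combined and
    p-values harmonic-mean-combined before classification.
    """
    rng = np.random.default_rng(config.seed)
    plan = build_standardization_plan(
        table, site, cap=config.standardization_cap, seed=config.seed
    )
    per_metric: dict[tuple[str, str], list[EffectTest]] = {}
    for combo in plan.plot_combinations:
        sub = replicate_table(table, plan, combo)
        n_base = rarefaction_base_n(sub, site)
        _, per_p = alpha_metrics(sub, site, "pasture", n_base)
        _, per_m = alpha_metrics(sub, site, "meadow", n_base)
        for m in GAMMA_TEST_METRICS:
            eff = alpha_scale_test(
                per_p[m], per_m[m], site=site, taxon_group=taxon_group,
                metric=m, n_perm=config.alpha_n_perm, rng=rng,
            )
            per_metric.setdefault((m, "alpha"), []).append(eff)
        perm = site_permutation_tests(
            sub, site, taxon_group=taxon_group, n_perm=config.n_perm, rng=rng,
            statistic=config.statistic, unit=config.permutation_unit,
            n_base=n_base,
        )
        for m, eff in perm.items():
            per_metric.setdefault((m, eff.scale), []).append(eff)

    combined = {
        key: CombinedResult(metric=key[0], scale=key[1], replicates=effs)
        for key, effs in per_metric.items()
    }
    classifications = {
        m: classify_scale_dependence(
            combined[(m, "alpha")], combined[(m, "gamma")], config.alpha_level
        )
        for m in GAMMA_TEST_METRICS
    }
    return SiteTaxonResult(site, taxon_group, plan, combined, classifications)
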