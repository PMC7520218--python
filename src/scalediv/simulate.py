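"""Synthetic grassland/OTU communities with a known two-treatment design.

Emulates the field design of the pasture-vs-meadow study system: sites, each
with up to three 10 m × 10 m plots per management type, each plot holding
ten 1 m² subplots.  Three community components are independently
controllable and map one-to-one onto the diversity partition:

* **density** — subplot totals are Poisson(λ); ``density_mult`` scales λ for
  pastures and moves N without touching the SAD (so S_n is unaffected);
* **SAD shape / evenness** — the regional species-abundance distribution is
  lognormal, p_i ∝ exp(σ·z_i) for shared standard-normal deviates z_i;
  ``sigma_mult`` rescales σ for pastures, reshaping evenness (S_PIE) while
  both groups keep the same species ranks and the same expected N;
* **intraspecific spatial aggregation** — each subplot realises the regional
  SAD *shape* exactly, but which species occupies which abundance rank is
  decided by a noisy suitability score ln p_i + η/√θ.  Large θ locks ranks
  to the regional ranks (all subplots alike, β → 1); small θ decorrelates
  species identities across subplots (clumping), raising β-S_n while leaving
  every α-scale metric distribution unchanged.  ``theta_mult`` scales θ for
  pastures.

Because the abundance values per subplot are always the sorted regional SAD,
the three knobs are orthogonal: λ only moves N, σ only moves evenness, θ
only moves spatial aggregation.  An overdispersion model that perturbed the
abundance *values* as well (e.g. a species-level Dirichlet-multinomial)
would confound aggregation with subplot-level evenness.

Multipliers of 1 give an exact null: both groups are draws from one
generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data_model import CommunityTable, SampleMeta

#: Dirichlet concentration treated as the "no aggregation" infinite limit
THETA_INFINITE = 1e8

#: site LUI categories cycled over sites (study design: 2 low, 2 intermediate,
#: 1 high across five sites)
_LUI_CYCLE = ("low", "low", "intermediate", "intermediate", "high")


@dataclass(frozen=True)
class TreatmentMultipliers:
    """Per-component multipliers applied to the pasture group."""

    density_mult: float = 1.0
    sigma_mult: float = 1.0
    theta_mult: float = 1.0

    def is_null(self) -> bool:
        return self.density_mult == self.sigma_mult == self.theta_mult == 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Design and community parameters for one synthetic experiment.

    Defaults mirror the balanced field design (5 sites × 2 management types
    × 3 plots × 10 subplots of 1 m²) with a 100-species regional pool, a
    lognormal SAD of shape σ = 1, ~100 individuals per subplot and moderate
    aggregation (θ = 5).
    """

    seed: int
    n_sites: int = 5
    plots_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"pasture": 3, "meadow": 3}
    )
    subplots_per_plot: int = 10
    species_pool: int = 100
    sad_sigma: float = 1.0
    density_lambda: float = 100.0
    aggregation_theta: float = 5.0
    treatment: TreatmentMultipliers = field(default_factory=TreatmentMultipliers)
    #: optional per-site plot counts, e.g. [{"pasture": 3, "meadow": 1}, ...];
    #: overrides plots_per_group site by site (shorter lists cycle)
    site_designs: Sequence[Mapping[str, int]] | None = None

    def __post_init__(self) -> None:
        if self.species_pool < 2:
            raise ValueError("species_pool must be >= 2")
        if self.sad_sigma < 0:
            raise ValueError("sad_sigma must be >= 0")
        for v in (self.density_lambda, self.aggregation_theta):
            if v <= 0:
                raise ValueError("density_lambda and aggregation_theta must be > 0")

    def plots_for(self, site_index: int, management: str) -> int:
        if self.site_designs:
            d = self.site_designs[site_index % len(self.site_designs)]
            return int(d[management])
        return int(self.plots_per_group[management])


@dataclass
class TruthRecord:
    """Realised generator state for parameter-recovery tests."""

    config: SimulationConfig
    p_regional: dict[str, list[float]]          # per-site shared-pool SAD
    group_params: dict[str, dict[str, float]]   # "<site>/<management>" → λ, σ, θ

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": _config_dict(self.config),
            "p_regional": self.p_regional,
            "group_params": self.group_params,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["plots_per_group"] = dict(config.plots_per_group)
    if config.site_designs is not None:
        d["site_designs"] = [dict(x) for x in config.site_designs]
    return d


# ---------------------------------------------------------------------------
# generator components
# ---------------------------------------------------------------------------


def draw_regional_sad(
    S_pool: int, sigma: float, seed_or_rng
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a lognormal regional SAD; returns (p, z).

    p_i ∝ exp(σ·z_i) with z_i ~ N(0,1).  The deviates z are returned so a
    treatment group can reuse them with a different σ (same pool, different
    evenness).  σ = 0 degenerates to the perfectly even SAD.
    """
    if S_pool < 2:
        raise ValueError("S_pool must be >= 2")
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng
    z = rng.standard_normal(S_pool)
    p = sad_from_deviates(z, sigma)
    return p, z


def sad_from_deviates(z: np.ndarray, sigma: float) -> np.ndarray:
    w = np.exp(sigma * np.asarray(z, dtype=float))
    return w / w.sum()


def subplot_probabilities(
    p_regional: np.ndarray, theta: float, rng: np.random.Generator, n_subplots: int
) -> np.ndarray:
    """Per-subplot species-probability vectors under aggregation θ.

    Each subplot's probability multiset is the regional SAD; which species
    occupies which abundance rank is decided by a noisy local-suitability
    score ``ln p_i + η_i / √θ`` (η iid standard normal, drawn fresh per
    subplot).  Large θ pins the ranking to the regional ranks (all subplots
    alike); small θ lets the noise dominate, so different subplots are
    dominated by different species — intraspecific clumping.  θ ≥
    THETA_INFINITE pins every subplot to p_regional exactly.
    """
    p = np.asarray(p_regional, dtype=float)
    S = p.size
    if theta >= THETA_INFINITE:
        return np.tile(p, (n_subplots, 1))
    scores = np.log(np.maximum(p, 1e-300)) + rng.standard_normal(
        (n_subplots, S)
    ) / np.sqrt(theta)
    # rank-assign: subplot's highest-scoring species receives the largest
    # regional abundance, and so on down the SAD
    order = np.argsort(-scores, axis=1, kind="stable")
    sorted_p = np.sort(p)[::-1]
    q = np.empty((n_subplots, S), dtype=float)
    rows = np.arange(n_subplots)[:, None]
    q[rows, order] = sorted_p[None, :]
    return q


def simulate_group(
    p_regional: np.ndarray,
    config: SimulationConfig,
    management: str,
    rng: np.random.Generator,
    n_subplots: int | None = None,
) -> np.ndarray:
    """Subplot × species count matrix for one (site, management) group.

    Pasture receives the treatment multipliers on λ (density) and θ
    (aggregation); meadow is the reference.  Each subplot draws its species
    probabilities, a Poisson(λ′) total, and multinomial counts.
    """
    is_pasture = management == "pasture"
    lam = config.density_lambda * (config.treatment.density_mult if is_pasture else 1.0)
    theta = config.aggregation_theta * (config.treatment.theta_mult if is_pasture else 1.0)
    if n_subplots is None:
        n_subplots = config.plots_per_group[management] * config.subplots_per_plot
    q = subplot_probabilities(p_regional, theta, rng, n_subplots)
    totals = rng.poisson(lam, size=n_subplots)
    counts = np.empty((n_subplots, q.shape[1]), dtype=float)
    for i in range(n_subplots):
        counts[i] = rng.multinomial(totals[i], q[i])
    return counts


def simulate_experiment(config: SimulationConfig) -> tuple[CommunityTable, TruthRecord]:
    """Assemble the full hierarchical experiment.

    One shared set of SAD deviates per site; pasture reshapes it with
    σ·sigma_mult.  All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    samples: list[SampleMeta] = []
    blocks: list[np.ndarray] = []
    p_record: dict[str, list[float]] = {}
    g_record: dict[str, dict[str, float]] = {}

    taxa = [f"sp{j + 1:04d}" for j in range(config.species_pool)]

    for si in range(config.n_sites):
        site = f"site{si + 1:02d}"
        lui = _LUI_CYCLE[si % len(_LUI_CYCLE)]
        p_ref, z = draw_regional_sad(config.species_pool, config.sad_sigma, rng)
        p_record[site] = np.round(p_ref, 12).tolist()
        for management in ("meadow", "pasture"):
            is_pasture = management == "pasture"
            sigma = config.sad_sigma * (config.treatment.sigma_mult if is_pasture else 1.0)
            p_group = sad_from_deviates(z, sigma) if is_pasture else p_ref
            n_plots = config.plots_for(si, management)
            n_sub = n_plots * config.subplots_per_plot
            counts = simulate_group(p_group, config, management, rng, n_subplots=n_sub)
            blocks.append(counts)
            g_record[f"{site}/{management}"] = {
                "lambda": config.density_lambda
                * (config.treatment.density_mult if is_pasture else 1.0),
                "sigma": sigma,
                "theta": config.aggregation_theta
                * (config.treatment.theta_mult if is_pasture else 1.0),
                "n_plots": float(n_plots),
            }
            for k in range(n_sub):
                plot = f"{management[0]}{k // config.subplots_per_plot + 1}"
                subplot = f"q{k % config.subplots_per_plot + 1:02d}"
                samples.append(
                    SampleMeta(
                        sample_id=f"{site}_{management}_{plot}_{subplot}",
                        site=site,
                        plot=f"{site}_{plot}",
                        subplot=subplot,
                        management=management,
                        lui_category=lui if is_pasture else "none",
                    )
                )

    table = CommunityTable(
        samples=samples,
        taxa=taxa,
        abundance=np.vstack(blocks),
        abundance_kind="counts",
    )
    truth = TruthRecord(config=config, p_regional=p_record, group_params=g_record)
    return table, truth
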