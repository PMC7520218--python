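"""End-to-end orchestration: ingest → prepare → metrics → inference → outputs.

A run processes one or more taxonomic groups (e.g. plants, fungi,
bacteria), each its own abundance + metadata table, and analyses every
site × group stratum independently.  Outputs are plain CSVs — metrics,
effects, scale-dependence classifications, filter report — plus a JSON
manifest recording the configuration and all derived seeds, which is
sufficient to reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    COUNTS,
    PERCENT_COVER,
    CommunityTable,
    FilterRule,
    StratumError,
    cover_to_counts,
    filter_rare_otus,
    pool_group,
    read_community_table,
)
from .inference import AnalysisConfig, run_site_taxon_analysis
from .metrics import group_metrics

logger = logging.getLogger("scalediv")


def substream(master_seed: int, *names: str) -> int:
    """Deterministic named child seed (< 2^31) from one master seed."""
    h = zlib.crc32(("/".join(names)).encode())
    return int(np.random.SeedSequence([master_seed, h]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class GroupInput:
    """One taxonomic group's input files and preparation switches."""

    name: str
    abundance_path: str
    meta_path: str
    format: str = "long"                  # "long" | "wide"
    abundance_kind: str = COUNTS
    apply_filter: bool = False
    filter_min_count: int = 5
    filter_min_sample_fraction: float = 0.01


@dataclass(frozen=True)
class RunConfig:
    groups: tuple[GroupInput, ...]
    output_dir: str
    seed: int = 0
    n_perm: int = 199
    alpha_level: float = 0.05
    standardization_cap: int = 200
    statistic: str = "lrr"
    permutation_unit: str = "subplot"
    skip_errors: bool = False


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML or JSON."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    groups = tuple(GroupInput(**g) for g in raw.pop("groups"))
    return RunConfig(groups=groups, **raw)


def prepare_group(table: CommunityTable, group: GroupInput):
    """Apply the group's preparation rule: cover→counts or prevalence filter."""
    report = None
    if table.abundance_kind == PERCENT_COVER:
        if group.apply_filter:
            raise ValueError(
                f"group {group.name!r}: prevalence filter cannot be applied to "
                "a percent_cover table; discretise first"
            )
        table = cover_to_counts(table)
    elif group.apply_filter:
        rule = FilterRule(group.filter_min_count, group.filter_min_sample_fraction)
        table, report = filter_rare_otus(table, rule)
    return table, report


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the paths of the written outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)

    metric_rows, effect_rows, class_rows, filter_frames = [], [], [], []
    seeds: dict[str, int] = {}
    try:
        for group in config.groups:
            table = read_community_table(
                group.abundance_path, format=group.format, meta_path=group.meta_path,
                abundance_kind=group.abundance_kind,
            )
            table, report = prepare_group(table, group)
            if report is not None:
                report = report.copy()
                report.insert(0, "taxon_group", group.name)
                filter_frames.append(report)
            for site in table.sites():
                stratum = f"{group.name}/{site}"
                seed = substream(config.seed, "analysis", group.name, site)
                seeds[stratum] = seed
                try:
                    _analyse_stratum(
                        table, site, group.name, config, seed,
                        metric_rows, effect_rows, class_rows,
                    )
                except (StratumError, ValueError) as exc:
                    if not config.skip_errors:
                        raise
                    logger.error("stratum %s skipped: %s", stratum, exc)

        paths = _write_outputs(
            out, config, seeds, metric_rows, effect_rows, class_rows, filter_frames
        )
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
    return paths


def _analyse_stratum(table, site, group_name, config, seed,
                     metric_rows, effect_rows, class_rows) -> None:
    from .metrics import rarefaction_base_n

    n_base = rarefaction_base_n(table, site)
    for management in ("pasture", "meadow"):
        alpha, gamma, beta, _ = group_metrics(table, site, management, n_base)
        for ms in (alpha, gamma):
            for m in ("N", "S", "S_n", "PIE", "S_PIE"):
                metric_rows.append(
                    dict(site=site, taxon_group=group_name, management=management,
                         scale=ms.scale, metric=m, value=getattr(ms, m),
                         n_base=ms.n_base, n_subplots=ms.n_subplots)
                )
        for m in ("beta_S", "beta_S_n", "beta_S_PIE"):
            metric_rows.append(
                dict(site=site, taxon_group=group_name, management=management,
                     scale="beta", metric=m, value=getattr(beta, m),
                     n_base=beta.n_base, n_subplots=alpha.n_subplots)
            )

    result = run_site_taxon_analysis(
        table, site, taxon_group=group_name,
        config=AnalysisConfig(
            n_perm=config.n_perm, alpha_level=config.alpha_level,
            standardization_cap=config.standardization_cap, seed=seed,
            statistic=config.statistic, permutation_unit=config.permutation_unit,
        ),
    )
    for (metric, scale), comb in sorted(result.combined.items()):
        effect_rows.append(
            dict(site=site, taxon_group=group_name, metric=metric, scale=scale,
                 lrr=comb.lrr, statistic=comb.replicates[0].statistic,
                 p=comb.p_value, n_perm=config.n_perm,
                 n_replicates=len(comb.replicates))
        )
    for metric, cls in sorted(result.classifications.items()):
        class_rows.append(
            dict(site=site, taxon_group=group_name, metric=metric,
                 category=cls.category, lrr_alpha=cls.lrr_alpha,
                 lrr_gamma=cls.lrr_gamma, p_alpha=cls.p_alpha,
                 p_gamma=cls.p_gamma)
        )


def _write_outputs(out, config, seeds, metric_rows, effect_rows, class_rows,
                   filter_frames) -> dict[str, Path]:
    paths = {
        "metrics": out / "metrics.csv",
        "effects": out / "effects.csv",
        "classification": out / "classification.csv",
        "manifest": out / "manifest.json",
    }
    pd.DataFrame(metric_rows).to_csv(paths["metrics"], index=False)
    pd.DataFrame(effect_rows).to_csv(paths["effects"], index=False)
    pd.DataFrame(class_rows).to_csv(paths["classification"], index=False)
    if filter_frames:
        paths["filter_report"] = out / "filter_report.csv"
        pd.concat(filter_frames, ignore_index=True).to_csv(
            paths["filter_report"], index=False
        )
    manifest = {
        "config": dataclasses.asdict(config),
        "seeds": seeds,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


def summarize_quadrants(classification: pd.DataFrame) -> dict:
    """Count scale-dependence categories over all site × taxon × metric cases.

    Returns per-category counts and the fraction of qualitative reversals
    among determined cases (0 when the table is empty).
    """
    counts: dict[str, int] = {}
    if len(classification):
        counts = classification["category"].value_counts().to_dict()
    determined = sum(v for k, v in counts.items() if k != "undetermined")
    reversals = counts.get("qualitative_reversal", 0)
    return {
        "counts": counts,
        "n_cases": int(len(classification)),
        "reversal_fraction": (reversals / determined) if determined else 0.0,
    }
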