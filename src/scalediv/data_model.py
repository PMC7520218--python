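"""Hierarchical community tables and data-preparation rules.

The sampling hierarchy is site > plot > subplot (1 m²), with each subplot
assigned to one of two land-management (LM) types, *pasture* or *meadow*.
Abundance is either percent cover (plants) or read counts (soil OTUs).
This module defines the in-memory containers, readers/writers for long- and
wide-format tables, the prevalence filter applied to OTU count tables, the
cover→pseudo-count discretisation, and pooling of subplots to the γ-scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("scalediv")

MANAGEMENT_LEVELS = ("pasture", "meadow")
LUI_CATEGORIES = ("low", "intermediate", "high", "none")

COUNTS = "counts"
PERCENT_COVER = "percent_cover"

#: columns expected in a long-format abundance file
LONG_COLUMNS = ("sample_id", "taxon", "abundance")
#: columns expected in a sample-metadata file
META_COLUMNS = ("sample_id", "site", "plot", "subplot", "management")


class FormatError(ValueError):
    """An input file does not have the expected layout."""


class ValidationError(ValueError):
    """Input values violate a container invariant."""


class StratumError(ValueError):
    """A requested (site, management) stratum is absent or unusable."""


@dataclass(frozen=True)
class SampleMeta:
    """Identity and design position of one subplot sample."""

    sample_id: str
    site: str
    plot: str
    subplot: str
    management: str
    lui_category: str = "none"

    def __post_init__(self) -> None:
        if self.management not in MANAGEMENT_LEVELS:
            raise ValidationError(
                f"management must be one of {MANAGEMENT_LEVELS}, "
                f"got {self.management!r} for sample {self.sample_id!r}"
            )
        if self.lui_category not in LUI_CATEGORIES:
            raise ValidationError(
                f"lui_category must be one of {LUI_CATEGORIES}, "
                f"got {self.lui_category!r}"
            )


@dataclass(frozen=True)
class FilterRule:
    """Prevalence rule for dropping rare OTUs.

    A taxon is kept iff its count exceeds ``min_count`` (strictly) in at
    least ``ceil(min_sample_fraction * n_samples)`` samples.
    """

    min_count: int = 5
    min_sample_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValidationError("min_count must be >= 0")
        if not (0.0 < self.min_sample_fraction <= 1.0):
            raise ValidationError("min_sample_fraction must be in (0, 1]")


@dataclass
class CommunityTable:
    """Subplot × taxon abundance matrix with aligned sample metadata.

    ``abundance[i, j]`` is the abundance of taxon ``taxa[j]`` in sample
    ``samples[i]``.  Count tables must hold non-negative integers; cover
    tables hold non-negative percentages.
    """

    samples: list[SampleMeta]
    taxa: list[str]
    abundance: np.ndarray
    abundance_kind: str = COUNTS

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.ndim != 2:
            raise ValidationError("abundance must be a 2-D matrix")
        if self.abundance.shape != (len(self.samples), len(self.taxa)):
            raise ValidationError(
                f"abundance shape {self.abundance.shape} does not match "
                f"{len(self.samples)} samples × {len(self.taxa)} taxa"
            )
        if self.abundance_kind not in (COUNTS, PERCENT_COVER):
            raise ValidationError(f"unknown abundance_kind {self.abundance_kind!r}")
        if np.any(self.abundance < 0):
            raise ValidationError("abundance contains negative entries")
        if not np.all(np.isfinite(self.abundance)):
            raise ValidationError("abundance contains non-finite entries")
        if self.abundance_kind == COUNTS and not np.allclose(
            self.abundance, np.round(self.abundance)
        ):
            raise ValidationError("counts table contains non-integer entries")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in table")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon identifier in table")

    # ---- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta_frame(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame (one row per sample, table order)."""
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "site": [s.site for s in self.samples],
                "plot": [s.plot for s in self.samples],
                "subplot": [s.subplot for s in self.samples],
                "management": [s.management for s in self.samples],
                "lui_category": [s.lui_category for s in self.samples],
            }
        )

    def to_wide_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundance, index=self.sample_ids, columns=list(self.taxa)
        )

    def sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.site, None)
        return list(seen)

    def select(self, mask: Sequence[bool] | np.ndarray) -> "CommunityTable":
        """Row-subset of the table (taxa unchanged)."""
        mask = np.asarray(mask, dtype=bool)
        samples = [s for s, keep in zip(self.samples, mask) if keep]
        return CommunityTable(
            samples=samples,
            taxa=list(self.taxa),
            abundance=self.abundance[mask],
            abundance_kind=self.abundance_kind,
        )

    def group_mask(self, site: str, management: str) -> np.ndarray:
        return np.array(
            [s.site == site and s.management == management for s in self.samples],
            dtype=bool,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def _meta_from_frame(meta: pd.DataFrame) -> dict[str, SampleMeta]:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata file is missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id in metadata: {dupes[:5]}")
    out: dict[str, SampleMeta] = {}
    for row in meta.itertuples(index=False):
        d = row._asdict()
        out[str(d["sample_id"])] = SampleMeta(
            sample_id=str(d["sample_id"]),
            site=str(d["site"]),
            plot=str(d["plot"]),
            subplot=str(d["subplot"]),
            management=str(d["management"]),
            lui_category=str(d.get("lui_category", "none") or "none"),
        )
    return out


def read_community_table(
    path: str | Path,
    format: str = "long",
    meta_path: str | Path | None = None,
    abundance_kind: str = COUNTS,
) -> CommunityTable:
    """Read an abundance table plus sample metadata.

    ``format='long'`` expects columns (sample_id, taxon, abundance);
    ``format='wide'`` expects sample rows (first column = sample_id) with one
    column per taxon.  Every sample in the abundance file must have a
    metadata row; all-zero taxa are retained (logged).
    """
    if meta_path is None:
        raise FormatError("meta_path is required")
    meta = _meta_from_frame(_read_table(meta_path))

    if format == "long":
        df = _read_table(path)
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"long-format file is missing columns {missing}")
        if df.duplicated(subset=["sample_id", "taxon"]).any():
            raise ValidationError("duplicate (sample_id, taxon) rows in long file")
        wide = (
            df.pivot(index="sample_id", columns="taxon", values="abundance")
            .fillna(0.0)
            .sort_index(axis=1)
        )
    elif format == "wide":
        df = _read_table(path)
        wide = df.set_index(df.columns[0]).sort_index(axis=1)
        wide.index = wide.index.astype(str)
    else:
        raise FormatError(f"unknown format {format!r}")

    unknown = [sid for sid in wide.index if str(sid) not in meta]
    if unknown:
        raise ValidationError(f"samples with no metadata row: {unknown[:5]}")

    # preserve metadata-file ordering for samples present in the table
    order = [sid for sid in meta if sid in set(map(str, wide.index))]
    wide = wide.loc[order]

    zero_taxa = [t for t in wide.columns if (wide[t] == 0).all()]
    if zero_taxa:
        logger.info("retaining %d all-zero taxa: %s", len(zero_taxa), zero_taxa[:5])

    return CommunityTable(
        samples=[meta[str(sid)] for sid in wide.index],
        taxa=[str(t) for t in wide.columns],
        abundance=wide.to_numpy(dtype=float),
        abundance_kind=abundance_kind,
    )


def write_community_table(
    table: CommunityTable, path: str | Path, meta_path: str | Path
) -> None:
    """Write the long-format abundance TSV and the metadata TSV."""
    rows = []
    for i, s in enumerate(table.samples):
        for j, t in enumerate(table.taxa):
            v = table.abundance[i, j]
            if v != 0:
                rows.append((s.sample_id, t, int(v) if v == int(v) else v))
    pd.DataFrame(rows, columns=list(LONG_COLUMNS)).to_csv(path, sep="\t", index=False)
    table.meta_frame().to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preparation rules
# ---------------------------------------------------------------------------


def prevalence_threshold(rule: FilterRule, n_samples: int) -> int:
    """Number of qualifying samples required to keep a taxon (never zero)."""
    return max(1, int(np.ceil(rule.min_sample_fraction * n_samples)))


def filter_rare_otus(
    table: CommunityTable, rule: FilterRule = FilterRule()
) -> tuple[CommunityTable, pd.DataFrame]:
    """Drop rare OTUs by prevalence; returns (filtered table, report).

    Keeps taxon *j* iff the number of samples where its count is strictly
    greater than ``rule.min_count`` reaches the prevalence threshold.  The
    sample set and all retained cells are unchanged.  The report has one row
    per input taxon: (taxon, prevalence, kept).
    """
    if table.abundance_kind != COUNTS:
        raise TypeError("prevalence filter applies to count tables only")
    prevalence = (table.abundance > rule.min_count).sum(axis=0)
    needed = prevalence_threshold(rule, table.n_samples)
    kept = prevalence >= needed
    report = pd.DataFrame(
        {"taxon": table.taxa, "prevalence": prevalence.astype(int), "kept": kept}
    )
    logger.info(
        "prevalence filter (>%d in >=%d/%d samples): kept %d of %d taxa",
        rule.min_count, needed, table.n_samples, int(kept.sum()), table.n_taxa,
    )
    filtered = CommunityTable(
        samples=list(table.samples),
        taxa=[t for t, k in zip(table.taxa, kept) if k],
        abundance=table.abundance[:, kept],
        abundance_kind=COUNTS,
    )
    return filtered, report


def cover_to_counts(table: CommunityTable) -> CommunityTable:
    """Discretise percent cover to integer pseudo-individuals.

    Each cell becomes ``round(value)``, except that positive covers below
    0.5% map to 1 so presence is never lost.  Rarefaction and PIE require
    discrete individuals; visually estimated cover is treated as a per-cell
    individual count at 1% resolution.
    """
    if table.abundance_kind != PERCENT_COVER:
        raise TypeError("cover_to_counts applies to percent_cover tables only")
    counts = np.round(table.abundance)
    counts[(table.abundance > 0) & (counts < 1)] = 1.0
    return CommunityTable(
        samples=list(table.samples),
        taxa=list(table.taxa),
        abundance=counts,
        abundance_kind=COUNTS,
    )


def pool_group(table: CommunityTable, site: str, management: str) -> np.ndarray:
    """Sum subplot rows of one (site, management) stratum to the γ-scale."""
    mask = table.group_mask(site, management)
    if not mask.any():
        raise StratumError(f"no samples for site={site!r}, management={management!r}")
    return table.abundance[mask].sum(axis=0)
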