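"""Shared fixtures: tiny hand-built community tables."""

from __future__ import annotations

import numpy as np
import pytest

from scalediv.data_model import CommunityTable, SampleMeta


def make_table(rows, taxa, metas=None, kind="counts", site="s1"):
    """Build a CommunityTable from a list of abundance rows.

    ``metas``: list of (plot, management) pairs; defaults to alternating
    pasture/meadow subplots in one plot per management.
    """
    rows = np.asarray(rows, dtype=float)
    if metas is None:
        metas = [("p1", "pasture") if i % 2 == 0 else ("m1", "meadow")
                 for i in range(rows.shape[0])]
    samples = [
        SampleMeta(
            sample_id=f"{site}_{plot}_q{i}",
            site=site, plot=f"{site}_{plot}", subplot=f"q{i}",
            management=management,
        )
        for i, (plot, management) in enumerate(metas)
    ]
    return CommunityTable(samples=samples, taxa=list(taxa), abundance=rows,
                          abundance_kind=kind)


@pytest.fixture
def two_group_table():
    """One site, 3 pasture + 3 meadow subplots, 4 taxa."""
    rows = [
        [4, 2, 1, 0],
        [3, 3, 0, 1],
        [5, 1, 1, 0],
        [2, 2, 2, 1],
        [4, 1, 1, 1],
        [3, 2, 1, 0],
    ]
    metas = [("p1", "pasture")] * 3 + [("m1", "meadow")] * 3
    return make_table(rows, ["A", "B", "C", "D"], metas)
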