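"""Shared fixtures: simulated studies and mapped results (session-scoped,
because the full simulate→map round trip costs a couple of seconds)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dualqtl.pipeline import classify_study, map_gene_channel, simulate_study
from dualqtl.pool_io import MarkerList, PoolMeta, PooledCounts


@pytest.fixture(scope="session")
def study():
    """Default-scale study (4 planted QTL classes, one replicate)."""
    return simulate_study(seed=11)


@pytest.fixture(scope="session")
def mapped(study):
    """Both channels mapped and merged for the default study."""
    return {ch: map_gene_channel(study.pools[ch]) for ch in ("mRNA", "protein")}


@pytest.fixture(scope="session")
def classified(study, mapped):
    return classify_study(mapped["mRNA"], mapped["protein"], gene=study.gene)


@pytest.fixture
def tiny_markers():
    return MarkerList(
        pd.DataFrame(
            {
                "chrom": ["chrI", "chrI", "chrI"],
                "pos": [100, 200, 300],
                "ref": ["A", "C", "G"],
                "alt": ["T", "G", "A"],
            }
        )
    )


@pytest.fixture
def tiny_counts(tiny_markers):
    return PooledCounts(
        tiny_markers,
        ref=np.array([5, 9, 0]),
        alt=np.array([5, 1, 0]),
        meta=PoolMeta(gene="GENE1", channel="GFP", gate="high", replicate="1"),
    )
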