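"""Shared fixtures and brute-force per-base oracles.

The oracles label every base of a small chromosome in plain numpy boolean
arrays, independently of the package's interval algebra, so set operations
and densities can be checked exactly.
"""

from __future__ import annotations

import numpy as np
import pytest

from mobilome.annotation import TECopy
from mobilome.formats import RepeatHit
from mobilome.simulate import default_config, plant_genome


def make_hit(chrom="chr1", start=0, end=100, strand="+", family="famA",
             classification="DNA/Mariner-Tc1", cs=0, ce=None, div=1.0,
             link=1, score=100.0):
    if ce is None:
        ce = end - start
    return RepeatHit(chrom, start, end, strand, family, classification,
                     cs, ce, div, score, link)


def make_copy(chrom="chr1", start=0, end=1000, strand="+", family="famA",
              classification="DNA/Mariner-Tc1", div=1.0, cov=1.0,
              copy_id=None, cons_len=None):
    cons_len = cons_len or (end - start)
    copy_id = copy_id or f"{chrom}:{start}-{end}"
    frag = make_hit(chrom, start, end, strand, family, classification,
                    0, max(int(cov * cons_len), 1), div)
    return TECopy(copy_id, chrom, start, end, strand, family, classification,
                  fragments=[frag], divergence_pct=div, consensus_coverage=cov,
                  consensus_length=cons_len)


def mask_of(intervals, length):
    """Boolean per-base mask of a list of (start, end) pairs."""
    m = np.zeros(length, dtype=bool)
    for s, e in intervals:
        m[s:e] = True
    return m


@pytest.fixture(scope="session")
def default_sim():
    """The 5-Mb default synthetic genome (shared; treat as read-only)."""
    return plant_genome(default_config(seed=11))


@pytest.fixture(scope="session")
def default_sim_copies(default_sim):
    from mobilome.annotation import merge_fragments

    lengths = {r.id: r.length for r in default_sim.library}
    return merge_fragments(default_sim.hits, lengths)
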