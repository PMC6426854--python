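"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (brute-force substring scans,
per-read accumulation, exhaustive intersections) so they stay independent
of the indexed/seeded implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chaintrace._seq import random_genome, revcomp
from chaintrace.markers import ReadHit


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_genome(rng):
    return random_genome(5000, rng)


@pytest.fixture
def two_site_spec():
    from chaintrace import CommunitySpec

    return CommunitySpec(
        matrix_profiles={
            "CF": [("Ruminococcaceae", 0.45), ("Lachnospiraceae", 0.10)],
            "LIT": [("Corynebacteriaceae", 0.16), ("Staphylococcaceae", 0.12)],
            "MIL": [("Lactobacillaceae", 0.22), ("Bifidobacteriaceae", 0.14)],
            "PC": [("Lactobacillaceae", 0.903), ("Streptococcaceae", 0.087)],
        },
        n_sites=2,
        n_samples_per_matrix=10,
    )


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """One demo fixture directory shared by the pipeline tests."""
    from chaintrace import make_demo

    return make_demo(11, tmp_path_factory.mktemp("demo") / "chain")


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def naive_exact_hits(reads, reference: dict[str, str]) -> set[tuple]:
    """Every (read_id, contig, start, strand) exact full-length placement."""
    found = set()
    for rid, seq in reads.items() if isinstance(reads, dict) else (
        (r.read_id, r.seq) for r in reads
    ):
        for strand in "+-":
            oriented = seq if strand == "+" else revcomp(seq)
            if "N" in oriented:
                continue
            for name, ref in reference.items():
                start = 0
                while True:
                    i = ref.find(oriented, start)
                    if i < 0:
                        break
                    found.add((rid, name, i, strand))
                    start = i + 1
    return found


def naive_pileup(hits: list[ReadHit], reads: dict[str, str], reference: dict[str, str]):
    """Per-position base counts by direct per-read accumulation."""
    counts = {
        name: {b: [0] * len(seq) for b in "ACGT"}
        for name, seq in reference.items()
    }
    for h in hits:
        seq = reads[h.read_id]
        oriented = seq if h.strand == "+" else revcomp(seq)
        for offset, base in enumerate(oriented):
            if base in "ACGT":
                counts[h.contig][base][h.start + offset] += 1
    return counts


def brute_force_shared(presence, site: str, matrices) -> set[str]:
    """Shared taxa by scanning every taxon against every matrix."""
    out = set()
    for taxon in presence.present.index:
        if all(bool(presence.present.loc[taxon, (site, m)]) for m in matrices):
            out.add(taxon)
    return out


def random_presence_map(rng, n_taxa=20, sites=("S1", "S2"), density=0.5):
    """A random PresenceMap for property tests."""
    from chaintrace.core import PresenceMap
    from chaintrace.profiles import MATRICES

    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    cols = pd.MultiIndex.from_tuples(
        [(s, m) for s in sites for m in MATRICES], names=["site", "matrix"]
    )
    present = pd.DataFrame(
        rng.random((n_taxa, len(cols))) < density, index=taxa, columns=cols
    )
    return PresenceMap(
        present=present,
        prevalence=present.astype(float),
        threshold=0.7,
        group_sizes={c: 10 for c in cols},
    )
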