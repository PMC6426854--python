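"""Core-microbiota sharing logic.

This implements the prevalence-based tracing used to argue transmission
along the production chain: a taxon (genus or 100%-identity OTU — the code
path is the same, the taxon labels are just finer) is "present" in a
(site, matrix) group when its prevalence there is strictly greater than a
threshold (default 70%); presence sets are intersected across matrices
within a site to count shared taxa, and a taxon qualifies at a site when
present in at least ``min_matrices_for_core`` (default 3) of the four
matrices. The resulting core table reports the mean relative abundance of
each qualifying taxon in every group where it is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ChainTraceError, ConfigError
from .profiles import MATRICES, AbundanceTable


@dataclass
class TracingConfig:
    """Thresholds of the sharing analysis.

    ``prevalence_threshold`` is compared strictly (prevalence > threshold),
    so with 10 samples per group a taxon needs at least 8 positives to pass
    the default 0.70.
    """

    prevalence_threshold: float = 0.70
    min_matrices_for_core: int = 3
    matrices: tuple[str, ...] = MATRICES
    mode: str = "prevalence"  # or "detection": present iff seen in any sample

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_threshold < 1:
            raise ConfigError("prevalence_threshold must be in (0, 1)")
        if not 1 <= self.min_matrices_for_core <= len(self.matrices):
            raise ConfigError("min_matrices_for_core out of range")
        if self.mode not in ("prevalence", "detection"):
            raise ConfigError(f"unknown presence mode {self.mode!r}")


@dataclass
class PresenceMap:
    """Boolean taxon x (site, matrix) presence, with the prevalences behind it."""

    present: pd.DataFrame  # index taxa, columns MultiIndex (site, matrix)
    prevalence: pd.DataFrame  # same shape, fractions in [0, 1]
    threshold: float
    group_sizes: dict = field(default_factory=dict)
    mode: str = "prevalence"

    @property
    def sites(self) -> list[str]:
        return sorted(set(self.present.columns.get_level_values(0)))

    def matrices_at(self, site: str) -> list[str]:
        cols = [m for s, m in self.present.columns if s == site]
        return sorted(cols, key=MATRICES.index)

    def present_set(self, site: str, matrix: str) -> set[str]:
        if (site, matrix) not in self.present.columns:
            raise ChainTraceError(f"unknown group ({site}, {matrix})")
        col = self.present[(site, matrix)]
        return set(col.index[col])

    def to_frame(self) -> pd.DataFrame:
        """Tidy (taxon, site, matrix, prevalence, present) rows for TSV export."""
        rows = []
        for taxon in self.present.index:
            for site, matrix in self.present.columns:
                rows.append(
                    (
                        taxon,
                        site,
                        matrix,
                        float(self.prevalence.loc[taxon, (site, matrix)]),
                        bool(self.present.loc[taxon, (site, matrix)]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["taxon", "site", "matrix", "prevalence", "present"]
        )


def prevalence_filter(
    table: AbundanceTable, config: TracingConfig | None = None
) -> PresenceMap:
    """Per-(site, matrix) presence by strict prevalence comparison.

    In the default ``prevalence`` mode, presence means prevalence strictly
    above ``config.prevalence_threshold``; in ``detection`` mode, presence
    means detected (> 0 abundance) in at least one sample of the group.
    """
    config = config or TracingConfig()
    groups = table.groups()
    if not groups:
        raise ChainTraceError("table has no samples")
    for site, matrix in groups:
        if len(table.group_samples(site, matrix)) == 0:
            raise ChainTraceError(f"empty group ({site}, {matrix})")

    prev_cols = {}
    sizes = {}
    for site, matrix in groups:
        samples = table.group_samples(site, matrix)
        sizes[(site, matrix)] = len(samples)
        sub = table.values.loc[samples]
        prev_cols[(site, matrix)] = (sub > 0).mean(axis=0)
    prevalence = pd.DataFrame(prev_cols)
    prevalence.columns = pd.MultiIndex.from_tuples(
        prev_cols.keys(), names=["site", "matrix"]
    )
    if config.mode == "prevalence":
        present = prevalence > config.prevalence_threshold
    else:
        present = prevalence > 0
    return PresenceMap(
        present=present,
        prevalence=prevalence,
        threshold=config.prevalence_threshold,
        group_sizes=sizes,
        mode=config.mode,
    )


def shared_across_matrices(presence: PresenceMap, site: str, matrices) -> set[str]:
    """Taxa present in every one of the given matrices at one site."""
    matrices = list(matrices)
    if not matrices:
        raise ChainTraceError("need at least one matrix")
    shared: set[str] | None = None
    for matrix in matrices:
        s = presence.present_set(site, matrix)
        shared = s if shared is None else shared & s
    return shared if shared is not None else set()


def pairwise_sharing_counts(
    presence: PresenceMap, site: str
) -> dict[tuple[str, ...], int]:
    """|shared set| for every combination of >= 2 matrices at one site."""
    matrices = presence.matrices_at(site)
    counts = {}
    for r in range(2, len(matrices) + 1):
        for combo in combinations(matrices, r):
            counts[combo] = len(shared_across_matrices(presence, site, combo))
    return counts


def mean_sharing_counts(presence: PresenceMap) -> dict[tuple[str, ...], float]:
    """Cross-site average of the per-site sharing counts.

    Combinations are averaged over the sites at which all member matrices
    were sampled.
    """
    per_site = {site: pairwise_sharing_counts(presence, site) for site in presence.sites}
    combos = sorted({c for d in per_site.values() for c in d}, key=lambda c: (len(c), c))
    return {
        combo: float(
            np.mean([d[combo] for d in per_site.values() if combo in d])
        )
        for combo in combos
    }


def site_sharing(
    presence: PresenceMap, min_matrices: int = 3
) -> tuple[pd.Series, dict[int, int]]:
    """Number of sites at which each taxon qualifies, plus the histogram.

    A taxon qualifies at a site when present in at least ``min_matrices``
    of the matrices sampled there (no matrix, PC included, is mandatory).
    """
    if min_matrices < 1:
        raise ChainTraceError("min_matrices must be >= 1")
    sites = presence.sites
    counts = pd.Series(0, index=presence.present.index, dtype=int)
    for site in sites:
        cols = [(site, m) for m in presence.matrices_at(site)]
        n_present = presence.present[cols].sum(axis=1)
        counts += (n_present >= min_matrices).astype(int)
    histogram: dict[int, int] = {}
    for n in counts:
        histogram[int(n)] = histogram.get(int(n), 0) + 1
    return counts.sort_index(), histogram


def core_table(
    table: AbundanceTable,
    presence: PresenceMap,
    config: TracingConfig | None = None,
) -> pd.DataFrame:
    """Mean relative abundance of core taxa per group where they are present.

    Rows are the taxa qualifying (>= ``min_matrices_for_core`` matrices) at
    at least one site; a cell holds the group's mean relative abundance
    where the taxon is present and NaN (rendered blank) where it is not.
    """
    config = config or TracingConfig()
    site_counts, _ = site_sharing(presence, config.min_matrices_for_core)
    qualifying = sorted(site_counts.index[site_counts >= 1])
    groups = [(s, m) for s, m in presence.present.columns]
    data = {}
    for site, matrix in groups:
        samples = table.group_samples(site, matrix)
        means = table.values.loc[samples, qualifying].mean(axis=0) if len(samples) else np.nan
        mask = presence.present.loc[qualifying, (site, matrix)]
        data[(site, matrix)] = means.where(mask)
    out = pd.DataFrame(data, index=qualifying)
    out.columns = pd.MultiIndex.from_tuples(groups, names=["site", "matrix"])
    return out
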