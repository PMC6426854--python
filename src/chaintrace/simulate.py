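"""Synthetic data with planted transmission structure.

The generator emulates the sampling design of a dairy production chain
study: several cheese-making sites, four matrices per site (CF cow feces,
LIT litter, MIL raw milk, PC fresh cheese), ten replicate samples per
matrix, with per-matrix community composition. On top of the background
communities, a :class:`TransmissionPlan` plants

* taxa that are carried along the chain (present, above the detection
  floor, in every sample of their planted (site, matrix) groups), and
* strains: genome variants differing from a reference by a known SNP set,
  from which read sets are simulated as mixtures.

Every downstream stage (prevalence filtering, sharing, primer tracing,
strict mapping, SNP profiles) can therefore be checked against exact
ground truth. All randomness flows from explicit integer seeds; a fixed
seed yields byte-identical tables, genomes, and reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import table1
from ._seq import BASES, random_genome, revcomp
from .core import PresenceMap
from .errors import ChainTraceError, ConfigError
from .profiles import MATRICES, AbundanceTable


# ---------------------------------------------------------------------------
# community / plan types
# ---------------------------------------------------------------------------


@dataclass
class CommunitySpec:
    """Background community design across sites and matrices.

    Parameters
    ----------
    matrix_profiles:
        Per matrix, the list of (taxon, mean relative abundance); means
        must sum to <= 1, the remainder is unassigned ("other") mass.
    n_sites:
        Number of production sites (labelled S1..Sn).
    n_samples_per_matrix:
        Replicate samples per (site, matrix) group; default 10, matching
        the per-matrix sampling depth of the study design.
    overdispersion:
        Dirichlet concentration scale; per-sample compositions are drawn
        from Dirichlet(overdispersion * means). Larger = tighter around
        the means. Default 50 gives realistic sample-to-sample spread
        (sd ~ 0.04 for a 0.9-mean taxon).
    detection_floor:
        Relative abundance strictly below which a taxon is recorded as 0
        (structural absence); this is what prevalence logic sees.
    """

    matrix_profiles: dict[str, list[tuple[str, float]]]
    n_sites: int = 2
    n_samples_per_matrix: int = 10
    overdispersion: float = 50.0
    detection_floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_samples_per_matrix < 1:
            raise ConfigError("need at least one site and one sample per matrix")
        if not 0 <= self.detection_floor < 1:
            raise ConfigError("detection_floor must be in [0, 1)")
        if self.overdispersion <= 0:
            raise ConfigError("overdispersion must be positive")
        for matrix, profile in self.matrix_profiles.items():
            if matrix not in MATRICES:
                raise ConfigError(f"unknown matrix {matrix!r}")
            total = sum(a for _, a in profile)
            if total > 1 + 1e-9:
                raise ConfigError(f"{matrix} mean abundances sum to {total} > 1")
            if any(a < 0 for _, a in profile):
                raise ConfigError(f"{matrix} has a negative mean abundance")

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1}" for i in range(self.n_sites))

    @property
    def matrices(self) -> tuple[str, ...]:
        return tuple(m for m in MATRICES if m in self.matrix_profiles)


@dataclass(frozen=True)
class PlantedTaxon:
    """A taxon carried along the chain: present in every sample of its groups."""

    taxon: str
    groups: frozenset  # of (site, matrix)
    carry_over: dict  # matrix -> relative abundance planted there


@dataclass(frozen=True)
class StrainModel:
    """A genome plus the SNP set separating it from its parent reference."""

    genome: str
    snps: frozenset  # of (position, ref_base, alt_base), 0-based
    label: str

    def __post_init__(self) -> None:
        n = len(self.genome)
        positions = [p for p, _, _ in self.snps]
        if len(set(positions)) != len(positions):
            raise ChainTraceError("duplicate SNP positions")
        for pos, ref, alt in self.snps:
            if not 0 <= pos < n:
                raise ChainTraceError(f"SNP position {pos} outside genome")
            if ref == alt:
                raise ChainTraceError(f"SNP at {pos} has ref == alt")
            if self.genome[pos] != alt:
                raise ChainTraceError(f"genome[{pos}] != recorded alt allele")


@dataclass(frozen=True)
class PlantedStrain:
    """A strain planted in specific (site, matrix) groups of the chain."""

    species: str
    genome_id: str
    strain: StrainModel
    groups: frozenset  # of (site, matrix) where the strain occurs
    mixture_proportion: float = 1.0  # share of that group's strain-level reads


@dataclass
class TransmissionPlan:
    """Ground truth: what was planted where, and the seed that fixes it all."""

    planted_taxa: list[PlantedTaxon] = field(default_factory=list)
    planted_strains: list[PlantedStrain] = field(default_factory=list)
    seed: int = 0

    def validate_against(self, spec: CommunitySpec) -> None:
        grid = {(s, m) for s in spec.sites for m in spec.matrices}
        for pt in self.planted_taxa:
            bad = set(pt.groups) - grid
            if bad:
                raise ConfigError(
                    f"planted taxon {pt.taxon!r} targets groups outside the "
                    f"site grid: {sorted(bad)}"
                )
            for matrix, c in pt.carry_over.items():
                if c <= spec.detection_floor:
                    raise ConfigError(
                        f"carry-over abundance {c} of {pt.taxon!r} in {matrix} "
                        f"does not exceed the detection floor"
                    )
        for ps in self.planted_strains:
            bad = set(ps.groups) - grid
            if bad:
                raise ConfigError(
                    f"planted strain {ps.strain.label!r} outside grid: {sorted(bad)}"
                )


# ---------------------------------------------------------------------------
# abundance-profile generation
# ---------------------------------------------------------------------------


def generate_chain_profiles(
    spec: CommunitySpec, plan: TransmissionPlan
) -> AbundanceTable:
    """Draw one relative-abundance table for the whole site x matrix grid.

    Background compositions come from a Dirichlet centered on the matrix
    means. Planted taxa are then set to their carry-over abundance in their
    planted groups (background rescaled to the remaining mass), so planted
    prevalence is exactly 1.0 there. Values strictly below the detection
    floor are zeroed.
    """
    plan.validate_against(spec)
    rng = np.random.default_rng(plan.seed)

    taxa: list[str] = []
    for matrix in spec.matrices:
        for name, _ in spec.matrix_profiles[matrix]:
            if name not in taxa:
                taxa.append(name)
    for pt in plan.planted_taxa:
        if pt.taxon not in taxa:
            taxa.append(pt.taxon)

    rows, meta_rows, index = [], [], []
    for site in spec.sites:
        for matrix in spec.matrices:
            profile = spec.matrix_profiles[matrix]
            planted_here = [
                pt
                for pt in plan.planted_taxa
                if (site, matrix) in pt.groups and matrix in pt.carry_over
            ]
            planted_names = {pt.taxon for pt in planted_here}
            total_c = sum(pt.carry_over[matrix] for pt in planted_here)
            if total_c > 1 + 1e-9:
                raise ConfigError(
                    f"carry-over abundances in ({site}, {matrix}) sum to "
                    f"{total_c} > 1"
                )
            bg = [(n, a) for n, a in profile if n not in planted_names]
            bg_means = np.array([a for _, a in bg], dtype=float)
            bg_total = bg_means.sum()
            resid = max(0.0, 1.0 - bg_total)
            for rep in range(1, spec.n_samples_per_matrix + 1):
                row = dict.fromkeys(taxa, 0.0)
                if bg_means.size:
                    alpha = np.concatenate([bg_means, [resid]]) \
                        if resid > 1e-12 else bg_means
                    draw = rng.dirichlet(spec.overdispersion * alpha)
                    comp = draw[: bg_means.size]
                    # planted mass squeezes background proportionally
                    comp = comp * (1.0 - total_c)
                    for (name, _), v in zip(bg, comp):
                        row[name] = float(v)
                for pt in planted_here:
                    row[pt.taxon] = float(pt.carry_over[matrix])
                for name, v in row.items():
                    if v < spec.detection_floor:
                        row[name] = 0.0
                rows.append([row[t] for t in taxa])
                meta_rows.append((site, matrix, rep))
                index.append(f"{site}_{matrix}_{rep:02d}")

    values = pd.DataFrame(rows, index=index, columns=taxa)
    meta = pd.DataFrame(
        meta_rows, index=index, columns=["site", "matrix", "replicate"]
    )
    values.index.name = meta.index.name = "sample_id"
    return AbundanceTable(values=values, meta=meta, relative=True)


# ---------------------------------------------------------------------------
# strain genomes and reads
# ---------------------------------------------------------------------------


def mutate_genome(genome: str, n_snps: int, seed: int, label: str = "variant") -> StrainModel:
    """Plant exactly ``n_snps`` substitutions at distinct random positions.

    The returned :class:`StrainModel` records the truth set of
    (position, reference base, alternate base) triples. Deterministic for a
    fixed seed.
    """
    if n_snps > len(genome):
        raise ChainTraceError(
            f"cannot place {n_snps} SNPs on a {len(genome)} bp genome"
        )
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(genome), size=n_snps, replace=False)
    arr = list(genome)
    truth = set()
    for pos in sorted(int(p) for p in positions):
        ref = arr[pos]
        alternatives = [b for b in BASES if b != ref]
        alt = alternatives[int(rng.integers(0, len(alternatives)))]
        arr[pos] = alt
        truth.add((pos, ref, alt))
    return StrainModel(genome="".join(arr), snps=frozenset(truth), label=label)


@dataclass
class ReadSimParams:
    """Read-simulation settings: length, count, substitution error rate, seed."""

    read_length: int = 100
    n_reads: int = 1000
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must be in [0, 1)")
        if self.read_length < 1 or self.n_reads < 0:
            raise ConfigError("read_length >= 1 and n_reads >= 0 required")


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated read plus its ground truth provenance."""

    read_id: str
    seq: str
    source: str  # strain label
    position: int  # 0-based start on the + strand of the source genome
    strand: str  # "+" or "-"
    n_errors: int


def simulate_reads(
    strains: list[tuple[StrainModel, float]], params: ReadSimParams
) -> list[SimulatedRead]:
    """Draw reads from a strain mixture, uniformly over positions and strands.

    Per-base substitution errors are applied at ``params.error_rate``; each
    read records its source strain, position, strand, and number of injected
    errors, so tests can separate error-free from error-bearing reads.
    """
    if not strains:
        raise ChainTraceError("empty strain list")
    props = np.array([p for _, p in strains], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ChainTraceError(f"mixture proportions sum to {props.sum()}, not 1")
    for strain, _ in strains:
        if len(strain.genome) < params.read_length:
            raise ChainTraceError(
                f"genome {strain.label!r} shorter than the read length"
            )
    rng = np.random.default_rng(params.seed)
    reads: list[SimulatedRead] = []
    choices = rng.choice(len(strains), size=params.n_reads, p=props)
    for i, which in enumerate(choices):
        strain, _ = strains[int(which)]
        start = int(rng.integers(0, len(strain.genome) - params.read_length + 1))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        seq = strain.genome[start : start + params.read_length]
        if strand == "-":
            seq = revcomp(seq)
        n_err = 0
        if params.error_rate > 0:
            mask = rng.random(params.read_length) < params.error_rate
            if mask.any():
                chars = list(seq)
                for pos in np.flatnonzero(mask):
                    old = chars[pos]
                    alts = [b for b in BASES if b != old]
                    chars[pos] = alts[int(rng.integers(0, len(alts)))]
                seq = "".join(chars)
                n_err = int(mask.sum())
        reads.append(
            SimulatedRead(
                read_id=f"read_{i:06d}",
                seq=seq,
                source=strain.label,
                position=start,
                strand=strand,
                n_errors=n_err,
            )
        )
    return reads


def table1_fixture() -> tuple[AbundanceTable, PresenceMap]:
    """The published 13-taxon core table as an abundance table + presence map.

    Each of the 20 (site, matrix) groups becomes one pseudo-sample holding
    the published group-mean relative abundances (fractions, not percent);
    dashes are absent (0 / not present). The presence map marks exactly the
    filled cells, with the published >70% threshold recorded.
    """
    frame = table1.core_table_frame()  # percent, NaN = dash
    present = frame.notna().T  # taxa x (site, matrix)
    prevalence = present.astype(float)
    values = (frame.fillna(0.0) / 100.0).copy()
    index = [f"{s}_{m}" for s, m in values.index]
    meta = pd.DataFrame(
        [(s, m, 1) for s, m in values.index],
        index=index,
        columns=["site", "matrix", "replicate"],
    )
    values.index = pd.Index(index, name="sample_id")
    meta.index.name = "sample_id"
    table = AbundanceTable(values=values, meta=meta, relative=True)
    pm = PresenceMap(
        present=present,
        prevalence=prevalence,
        threshold=0.7,
        group_sizes={g: 1 for g in present.columns},
        mode="prevalence",
    )
    return table, pm
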