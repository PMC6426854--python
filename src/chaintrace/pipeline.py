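"""End-to-end pipeline: config-driven staging, deterministic reports.

``run_pipeline`` executes the stages in the workflow order of the study
design — diversity, prevalence/sharing (core tracing), strain-marker
tracing (primers + in-silico PCR + strict mapping), SNP identity, ANI,
and the expression screen — writing versioned TSV reports and a JSON
manifest (inputs, parameters, seeds, output checksums). Re-running the
same config yields byte-identical outputs.

``make_demo`` emits a miniature two-site chain with two planted strains
(one carried through all four matrices, one only through feces and
litter) so the whole pipeline can run end to end against known truth in
seconds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression as expr
from . import profiles
from ._seq import random_genome
from .core import TracingConfig, core_table, mean_sharing_counts, pairwise_sharing_counts, prevalence_filter, site_sharing
from .errors import ConfigError, NoANISupportError
from .markers import Contig, MappingConfig, coverage_and_presence, design_primers, in_silico_pcr, strict_map
from .seqio import read_fasta, read_fastq, write_fasta, write_fastq
from .simulate import (
    CommunitySpec,
    PlantedStrain,
    PlantedTaxon,
    ReadSimParams,
    TransmissionPlan,
    generate_chain_profiles,
    mutate_genome,
    simulate_reads,
)
from .snp import ANIConfig, ani, pileup, same_strain, snp_profile, tolerant_map

ALL_STAGES = ("diversity", "trace_core", "trace_strain", "snp", "ani", "expression")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, resolvable from one YAML file."""

    base_dir: Path
    out_dir: Path
    seed: int | None = None
    stages: tuple[str, ...] = ALL_STAGES
    counts_table: Path | None = None
    relative_table: Path | None = None
    marker_genomes: dict = field(default_factory=dict)  # label -> fasta path
    background_genomes: list = field(default_factory=list)
    read_sets: dict = field(default_factory=dict)  # "<site>_<matrix>" -> fastq
    assemblies: dict = field(default_factory=dict)  # "<site>_<matrix>" -> fasta
    gene_counts: Path | None = None
    tracing: TracingConfig = field(default_factory=TracingConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    ani_config: ANIConfig = field(default_factory=ANIConfig)
    snp_params: dict = field(
        default_factory=lambda: {
            "min_cov": 5,
            "max_distance": 0.01,
            "min_homogeneity": 0.95,
            "min_joint": 50,
            "max_mismatch_frac": 0.05,
            "max_discordant": 10,
        }
    )
    fold: float = 3.0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        if self.seed is None:
            raise ConfigError(
                "config must name an explicit seed (stochastic stages such as "
                "rarefaction depend on it)"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def p(key_path, default=None):
            node = raw
            for k in key_path.split("."):
                if not isinstance(node, dict) or k not in node:
                    return default
                node = node[k]
            return node

        def resolve(v):
            return base / v if v is not None else None

        cfg = cls(
            base_dir=base,
            out_dir=base / p("out_dir", "out"),
            seed=p("seed"),
            stages=tuple(p("stages", list(ALL_STAGES))),
            counts_table=resolve(p("tables.counts")),
            relative_table=resolve(p("tables.relative")),
            marker_genomes={k: base / v for k, v in (p("strains.markers", {}) or {}).items()},
            background_genomes=[base / v for v in p("strains.background", []) or []],
            read_sets={k: base / v for k, v in (p("reads", {}) or {}).items()},
            assemblies={k: base / v for k, v in (p("assemblies", {}) or {}).items()},
            gene_counts=resolve(p("expression.counts")),
            tracing=TracingConfig(**(p("tracing", {}) or {})),
            mapping=MappingConfig(**(p("mapping", {}) or {})),
            ani_config=ANIConfig(**(p("ani", {}) or {})),
            fold=float(p("expression.fold", 3.0)),
        )
        cfg.snp_params.update(p("snp", {}) or {})
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; return {stage: [output paths]}."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[str]] = {}
    current = "setup"
    try:
        if "diversity" in config.stages:
            current = "diversity"
            if config.counts_table is None:
                raise ConfigError("diversity stage needs tables.counts")
            table = profiles.read_table(config.counts_table)
            div = profiles.sample_diversity(table, seed=config.seed)
            path = out_dir / "diversity.tsv"
            div.to_csv(path, sep="\t")
            outputs[current] = [str(path)]

        presence = None
        if "trace_core" in config.stages:
            current = "trace_core"
            src = config.relative_table or config.counts_table
            if src is None:
                raise ConfigError("trace_core stage needs an abundance table")
            table = profiles.read_table(src)
            presence = prevalence_filter(table, config.tracing)
            paths = []
            pm_path = out_dir / "presence_map.tsv"
            presence.to_frame().to_csv(pm_path, sep="\t", index=False)
            paths.append(pm_path)

            rows = []
            for site in presence.sites:
                for combo, n in sorted(pairwise_sharing_counts(presence, site).items()):
                    rows.append((site, "+".join(combo), n))
            for combo, n in mean_sharing_counts(presence).items():
                rows.append(("<mean>", "+".join(combo), n))
            sc_path = out_dir / "sharing_counts.tsv"
            pd.DataFrame(rows, columns=["site", "combination", "count"]).to_csv(
                sc_path, sep="\t", index=False
            )
            paths.append(sc_path)

            counts, histogram = site_sharing(presence, config.tracing.min_matrices_for_core)
            ss_path = out_dir / "site_sharing.tsv"
            counts.rename("qualifying_sites").to_csv(ss_path, sep="\t")
            paths.append(ss_path)

            ct = core_table(table, presence, config.tracing)
            ct_path = out_dir / "core_table.tsv"
            ct.to_csv(ct_path, sep="\t")
            paths.append(ct_path)
            outputs[current] = [str(p) for p in paths]

        if "trace_strain" in config.stages:
            current = "trace_strain"
            if not config.marker_genomes:
                raise ConfigError("trace_strain stage needs strains.markers")
            background = {}
            for path in config.background_genomes:
                background.update(read_fasta(path))
            genomes = {k: read_fasta(v) for k, v in sorted(config.marker_genomes.items())}
            markers = {}
            primer_rows = []
            for label, seqs in genomes.items():
                contig_id, seq = max(seqs.items(), key=lambda kv: (len(kv[1]), kv[0]))
                bg = dict(background)
                for other, oseqs in genomes.items():
                    if other != label:
                        bg.update({f"{other}:{k}": v for k, v in oseqs.items()})
                marker = design_primers(
                    Contig(id=contig_id, seq=seq, species=label), bg
                )
                markers[label] = marker
                for which, primer in (("F", marker.forward), ("R", marker.reverse)):
                    primer_rows.append(
                        (label, f"{label}_{which}", primer.seq, primer.start,
                         primer.tm, marker.product_length)
                    )
            primers_path = out_dir / "primers.tsv"
            pd.DataFrame(
                primer_rows,
                columns=["strain", "name", "sequence", "start", "tm", "product_length"],
            ).to_csv(primers_path, sep="\t", index=False)

            rows = []
            for label, marker in markers.items():
                reference = {marker.contig_id: marker.contig_seq}
                for group in sorted(set(config.read_sets) | set(config.assemblies)):
                    pcr_pos = None
                    if group in config.assemblies:
                        targets = read_fasta(config.assemblies[group])
                        pcr_pos = len(in_silico_pcr(marker, targets)) > 0
                    map_pos = breadth = depth = None
                    if group in config.read_sets:
                        reads = read_fastq(config.read_sets[group])
                        hits = strict_map(reads, reference, config.mapping)
                        breadth, depth, map_pos = coverage_and_presence(
                            hits, reference, config.mapping
                        )
                    rows.append((label, group, pcr_pos, map_pos, breadth, depth))
            sp_path = out_dir / "strain_presence.tsv"
            pd.DataFrame(
                rows,
                columns=["strain", "group", "pcr_presence", "map_presence",
                         "breadth", "depth"],
            ).to_csv(sp_path, sep="\t", index=False)
            outputs[current] = [str(primers_path), str(sp_path)]

        if "snp" in config.stages:
            current = "snp"
            if not config.marker_genomes or not config.read_sets:
                raise ConfigError("snp stage needs strains.markers and reads")
            sp = config.snp_params
            rows = []
            for label, fasta in sorted(config.marker_genomes.items()):
                reference = read_fasta(fasta)
                group_profiles = {}
                for group, fq in sorted(config.read_sets.items()):
                    reads = read_fastq(fq)
                    hits = tolerant_map(reads, reference, sp["max_mismatch_frac"])
                    if not hits:
                        continue
                    pile = pileup(hits, reads, reference)
                    prof = snp_profile(pile, min_cov=sp["min_cov"])
                    if prof.n_positions:
                        group_profiles[group] = prof
                for a, b in combinations(sorted(group_profiles), 2):
                    d = same_strain(
                        group_profiles[a],
                        group_profiles[b],
                        max_distance=sp["max_distance"],
                        min_homogeneity=sp["min_homogeneity"],
                        min_joint=sp["min_joint"],
                        max_discordant=sp["max_discordant"],
                    )
                    rows.append(
                        (label, a, b, d.distance, d.homogeneity_a,
                         d.homogeneity_b, d.joint_positions,
                         d.discordant_positions, d.verdict)
                    )
            snp_path = out_dir / "snp_decisions.tsv"
            pd.DataFrame(
                rows,
                columns=["strain", "group_a", "group_b", "distance",
                         "homogeneity_a", "homogeneity_b", "joint_positions",
                         "discordant_positions", "verdict"],
            ).to_csv(snp_path, sep="\t", index=False)
            outputs[current] = [str(snp_path)]

        if "ani" in config.stages:
            current = "ani"
            genomes = {
                label: "".join(read_fasta(path).values())
                for label, path in sorted(config.marker_genomes.items())
            }
            labels = sorted(genomes)
            mat = pd.DataFrame(index=labels, columns=labels, dtype=float)
            for a in labels:
                for b in labels:
                    try:
                        mat.loc[a, b] = ani(
                            genomes[a], genomes[b], config.ani_config
                        ).ani
                    except NoANISupportError:
                        mat.loc[a, b] = float("nan")  # no alignable fragments
            ani_path = out_dir / "ani_matrix.tsv"
            mat.to_csv(ani_path, sep="\t")
            outputs[current] = [str(ani_path)]

        if "expression" in config.stages and config.gene_counts is not None:
            current = "expression"
            counts = pd.read_csv(config.gene_counts, sep="\t")
            screen = expr.screen_table(counts, fold=config.fold)
            ex_path = out_dir / "expression_screen.tsv"
            screen.to_csv(ex_path, sep="\t")
            outputs[current] = [str(ex_path)]
    except Exception as e:  # noqa: BLE001 - annotate the failing stage
        raise type(e)(f"[stage {current}] {e}") from e

    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "tracing": config.tracing.__dict__.copy(),
            "mapping": config.mapping.__dict__,
            "ani": config.ani_config.__dict__,
            "snp": config.snp_params,
            "fold": config.fold,
        },
        "inputs": {
            "counts_table": str(config.counts_table),
            "relative_table": str(config.relative_table),
            "markers": {k: str(v) for k, v in config.marker_genomes.items()},
            "reads": {k: str(v) for k, v in config.read_sets.items()},
        },
        "outputs": {
            stage: {p: _sha256(Path(p)) for p in paths}
            for stage, paths in outputs.items()
        },
    }
    manifest["parameters"]["tracing"]["matrices"] = list(config.tracing.matrices)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = [str(out_dir / "manifest.json")]
    return outputs


# ---------------------------------------------------------------------------
# demo fixture
# ---------------------------------------------------------------------------

_DEMO_PROFILES = {
    # background family-level means, loosely shaped like the four matrices
    "CF": [("Ruminococcaceae", 0.446), ("Rikenellaceae", 0.113),
           ("Lachnospiraceae", 0.092), ("Bacteroidaceae", 0.060)],
    "LIT": [("Corynebacteriaceae", 0.162), ("Staphylococcaceae", 0.123),
            ("Aerococcaceae", 0.061), ("Lachnospiraceae", 0.050)],
    "MIL": [("Lactobacillaceae", 0.224), ("Bifidobacteriaceae", 0.135),
            ("Corynebacteriaceae", 0.075), ("Staphylococcaceae", 0.069)],
    "PC": [("Lactobacillaceae", 0.903), ("Streptococcaceae", 0.087)],
}


def make_demo(seed: int, out_dir: str | Path, genome_length: int = 10_000,
              reads_per_group: int = 1500) -> Path:
    """Write a miniature 2-site chain with planted truth; returns the dir.

    Site S1 carries strain ``chainwide`` in all four matrices (the pattern
    of a chain-wide colonizer) and strain ``partial`` only in CF and LIT;
    site S2 carries neither. The two strains live on unrelated genomes so
    exact mapping and PCR cannot cross-react; read sets mix the planted
    strains with an unrelated background species. Also writes per-group
    pseudo-assemblies (the genomes present in the group), a gene-count
    table with a few planted >3-fold genes, the ground-truth plan, and a
    ready-to-run ``config.yaml``.
    """
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "reads").mkdir(exist_ok=True)
    (out / "assemblies").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)

    spec = CommunitySpec(matrix_profiles=_DEMO_PROFILES, n_sites=2,
                         n_samples_per_matrix=10)
    chain_groups = frozenset(("S1", m) for m in spec.matrices)
    partial_groups = frozenset([("S1", "CF"), ("S1", "LIT")])
    chainwide = mutate_genome(random_genome(genome_length, rng), 0,
                              seed=seed, label="chainwide")
    partial = mutate_genome(random_genome(genome_length, rng), 50,
                            seed=seed + 1, label="partial")
    background_genome = random_genome(genome_length, rng)

    plan = TransmissionPlan(
        planted_taxa=[
            PlantedTaxon("Bifidobacterium_chainwide", chain_groups,
                         {"CF": 0.02, "LIT": 0.02, "MIL": 0.03, "PC": 0.01}),
            PlantedTaxon("Prevotella_partial", partial_groups,
                         {"CF": 0.05, "LIT": 0.03}),
        ],
        planted_strains=[
            PlantedStrain("Bifidobacterium sp.", "chainwide", chainwide,
                          chain_groups, 0.5),
            PlantedStrain("Prevotella sp.", "partial", partial,
                          partial_groups, 0.3),
        ],
        seed=seed,
    )
    table = generate_chain_profiles(spec, plan)
    profiles.write_table(table, out / "abundance.tsv")
    depth = 50_000
    counts = profiles.AbundanceTable(
        values=(table.values * depth).round().astype(int),
        meta=table.meta, relative=False,
    )
    profiles.write_table(counts, out / "abundance_counts.tsv")

    write_fasta({"chainwide_contig": chainwide.genome}, out / "genomes/chainwide.fasta")
    write_fasta({"partial_contig": partial.genome}, out / "genomes/partial.fasta")
    write_fasta({"background_contig": background_genome}, out / "genomes/background.fasta")

    read_paths, assembly_paths = {}, {}
    for gi, (site, matrix) in enumerate(
        (s, m) for s in spec.sites for m in spec.matrices
    ):
        group = f"{site}_{matrix}"
        mix = [(ps.strain, ps.mixture_proportion)
               for ps in plan.planted_strains if (site, matrix) in ps.groups]
        bg_prop = 1.0 - sum(p for _, p in mix)
        strains = mix + [(mutate_genome(background_genome, 0, 0, "background"), bg_prop)]
        params = ReadSimParams(read_length=100, n_reads=reads_per_group,
                               error_rate=0.0, seed=seed * 1000 + gi)
        reads = simulate_reads(strains, params)
        fq = out / f"reads/{group}.fastq"
        write_fastq(reads, fq)
        read_paths[group] = f"reads/{group}.fastq"
        assembly = {"background_contig": background_genome}
        for ps in plan.planted_strains:
            if (site, matrix) in ps.groups:
                assembly[f"{ps.genome_id}_contig"] = ps.strain.genome
        fa = out / f"assemblies/{group}.fasta"
        write_fasta(assembly, fa)
        assembly_paths[group] = f"assemblies/{group}.fasta"

    genes = []
    total_library = 1_000_000  # whole-library size; the table is a gene subset
    for i in range(30):
        length = int(rng.integers(300, 3000))
        base_reads = int(rng.integers(50, 500))
        planted_up = i < 5  # first five genes are truly >3-fold up
        factor = 5.0 if planted_up else float(rng.uniform(0.5, 2.0))
        genes.append((f"gene_{i:03d}", length, int(base_reads * factor),
                      base_reads, total_library, total_library, planted_up))
    gene_df = pd.DataFrame(
        genes, columns=["gene_id", "length_bp", "reads_condition",
                        "reads_control", "total_condition", "total_control",
                        "planted_up"],
    )
    gene_df.drop(columns="planted_up").to_csv(
        out / "gene_counts.tsv", sep="\t", index=False
    )

    truth = {
        "seed": seed,
        "planted_taxa": [
            {"taxon": pt.taxon, "groups": sorted(map(list, pt.groups)),
             "carry_over": pt.carry_over}
            for pt in plan.planted_taxa
        ],
        "planted_strains": [
            {"label": ps.strain.label, "species": ps.species,
             "groups": sorted(map(list, ps.groups)),
             "n_snps": len(ps.strain.snps),
             "mixture_proportion": ps.mixture_proportion}
            for ps in plan.planted_strains
        ],
        "expression_up_genes": gene_df.loc[gene_df.planted_up, "gene_id"].tolist(),
    }
    with open(out / "truth/plan.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)

    config = {
        "seed": seed,
        "out_dir": "out",
        "stages": list(ALL_STAGES),
        "tables": {"counts": "abundance_counts.tsv", "relative": "abundance.tsv"},
        "strains": {
            "markers": {"chainwide": "genomes/chainwide.fasta",
                        "partial": "genomes/partial.fasta"},
            "background": ["genomes/background.fasta"],
        },
        "reads": read_paths,
        "assemblies": assembly_paths,
        "expression": {"counts": "gene_counts.tsv", "fold": 3},
        "tracing": {"prevalence_threshold": 0.70, "min_matrices_for_core": 3},
        "mapping": {"identity_cutoff": 1.0, "coverage_cutoff": 1.0,
                    "min_reads_for_presence": 1, "min_breadth_for_presence": 0.5},
        "snp": {"min_cov": 5, "max_distance": 0.01, "min_homogeneity": 0.95,
                "min_joint": 50, "max_mismatch_frac": 0.05},
        "ani": {"fragment_length": 1020},
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return out
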