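"""Strain identity from SNP profiles and fragment-based ANI.

Two samples carry the same strain when reads mapped onto a shared
reference produce (i) homogeneous pileups — most positions dominated by a
single allele — and (ii) nearly identical variant-allele-frequency
profiles, summarized as the mean absolute frequency difference over
jointly covered positions. Isolate-level identity is confirmed by average
nucleotide identity (ANI) computed the fragment way: the query genome is
cut into consecutive ~1 kb fragments, each aligned to its best ungapped
match in the subject, fragments with at least 30% identity over at least
70% of their length are retained, and ANI is the mean identity of
retained fragments, averaged over both comparison directions.

All mapping here is ungapped and full read length; ambiguous reads (tied
best placements) are discarded for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import KmerIndex, count_mismatches, encode, revcomp
from .errors import ChainTraceError, ConfigError, NoANISupportError
from .markers import Contig, ReadHit, _read_items

_BIG = 1 << 30


def _ref_dict(reference) -> dict[str, str]:
    if isinstance(reference, dict):
        return dict(reference)
    return {c.id: c.seq for c in reference}


# ---------------------------------------------------------------------------
# mismatch-tolerant mapping
# ---------------------------------------------------------------------------


def tolerant_map(
    reads,
    reference,
    max_mismatch_frac: float = 0.05,
) -> list[ReadHit]:
    """Best unique ungapped full-length placement per read.

    A read maps where it aligns with at most
    ``floor(max_mismatch_frac * read length)`` substitutions; among
    qualifying placements (both strands) the fewest-mismatch one wins, and
    a tie leaves the read unmapped (ambiguous). Candidate placements are
    found by pigeonhole seeding — a read with at most m mismatches must
    contain an exact seed in one of m+1 equal chunks — and verified by
    direct mismatch counting, so the result matches a full scan.
    """
    items = _read_items(reads)
    seqs = _ref_dict(reference)
    if not items or not seqs:
        raise ChainTraceError("reads and reference must be non-empty")
    names = sorted(seqs)
    encoded = {name: encode(seqs[name]) for name in names}

    k_index = 13
    index: KmerIndex | None = None

    hits: list[ReadHit] = []
    for rid, seq in items:
        L = len(seq)
        max_mm = int(max_mismatch_frac * L)
        chunk = L // (max_mm + 1)
        candidates: set[tuple[str, int, str]] = set()
        if chunk >= 4:
            k = min(k_index, chunk)
            if index is None or index.k != k:
                index = KmerIndex(seqs, k)
            for strand in "+-":
                oriented = seq if strand == "+" else revcomp(seq)
                for j in range(max_mm + 1):
                    off = j * chunk
                    seed = oriented[off : off + k]
                    if len(seed) < k or "N" in seed:
                        continue
                    for name, pos in index.lookup(seed):
                        candidates.add((name, pos - off, strand))
        else:  # short reads / large budgets: scan every offset
            for strand in "+-":
                for name in names:
                    for pos in range(len(seqs[name]) - L + 1):
                        candidates.add((name, pos, strand))

        best_mm = _BIG
        best: list[tuple[str, int, str]] = []
        for name, pos, strand in sorted(candidates):
            oriented = seq if strand == "+" else revcomp(seq)
            mm = count_mismatches(encoded[name], encode(oriented), pos)
            if mm > max_mm:
                continue
            if mm < best_mm:
                best_mm, best = mm, [(name, pos, strand)]
            elif mm == best_mm:
                best.append((name, pos, strand))
        if len(best) == 1:
            name, pos, strand = best[0]
            hits.append(
                ReadHit(
                    read_id=rid,
                    contig=name,
                    start=pos,
                    end=pos + L,
                    strand=strand,
                    mismatches=best_mm,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# pileup and SNP profiles
# ---------------------------------------------------------------------------


@dataclass
class Pileup:
    """Per-position A/C/G/T counts over a reference contig set."""

    counts: dict  # contig -> (4, L) int array, rows A,C,G,T
    reference: dict  # contig -> sequence

    def coverage(self, contig: str) -> np.ndarray:
        return self.counts[contig].sum(axis=0)

    @property
    def total_bases(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def pileup(hits: list[ReadHit], reads, reference) -> Pileup:
    """Tally every aligned base at its reference position.

    Conservation holds by construction: the total of all tallied counts
    equals the total aligned read length (N bases are tallied too, in the
    coverage but not in any of the four base rows — they are dropped, so
    conservation is over non-N bases).
    """
    seqs = _ref_dict(reference)
    read_seq = dict(_read_items(reads))
    counts = {name: np.zeros((4, len(s)), dtype=np.int64) for name, s in seqs.items()}
    for h in hits:
        if h.contig not in counts:
            raise ChainTraceError(f"hit on unknown contig {h.contig!r}")
        if h.read_id not in read_seq:
            raise ChainTraceError(f"hit for unknown read {h.read_id!r}")
        seq = read_seq[h.read_id]
        oriented = seq if h.strand == "+" else revcomp(seq)
        if h.end - h.start != len(oriented) or h.end > len(seqs[h.contig]):
            raise ChainTraceError("hit inconsistent with read/reference")
        arr = encode(oriented)
        valid = arr != 4
        np.add.at(
            counts[h.contig],
            (arr[valid], np.arange(h.start, h.end)[valid]),
            1,
        )
    return Pileup(counts=counts, reference=seqs)


@dataclass
class SNPProfile:
    """Variant allele frequencies at sufficiently covered positions.

    ``positions`` maps contig -> integer array of positions with coverage
    >= ``min_cov``; ``vaf`` holds 1 - (reference base count / coverage) and
    ``major_freq`` the frequency of the most common base, both aligned with
    ``positions``.
    """

    reference_id: tuple
    positions: dict
    vaf: dict
    major_freq: dict
    min_cov: int

    @property
    def n_positions(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def homogeneity(self, major_threshold: float = 0.9) -> float:
        """Fraction of profiled positions dominated by one allele."""
        total = self.n_positions
        if total == 0:
            return float("nan")
        good = sum(
            int((m >= major_threshold).sum()) for m in self.major_freq.values()
        )
        return good / total


def snp_profile(pile: Pileup, min_cov: int = 5) -> SNPProfile:
    """Per-position variant allele frequency where coverage >= ``min_cov``."""
    positions, vaf, major = {}, {}, {}
    for name, counts in sorted(pile.counts.items()):
        cov = counts.sum(axis=0)
        keep = np.flatnonzero(cov >= min_cov)
        ref_arr = encode(pile.reference[name])
        ref_counts = np.zeros(len(ref_arr), dtype=np.int64)
        known = ref_arr != 4
        ref_counts[known] = counts[ref_arr[known], np.arange(len(ref_arr))[known]]
        positions[name] = keep
        with np.errstate(invalid="ignore"):
            vaf[name] = 1.0 - ref_counts[keep] / cov[keep]
            major[name] = counts[:, keep].max(axis=0) / cov[keep]
    return SNPProfile(
        reference_id=tuple(sorted(pile.reference)),
        positions=positions,
        vaf=vaf,
        major_freq=major,
        min_cov=min_cov,
    )


@dataclass(frozen=True)
class IdentityDecision:
    distance: float
    homogeneity_a: float
    homogeneity_b: float
    joint_positions: int
    discordant_positions: int
    verdict: str  # "same-strain" | "different-strain" | "insufficient-overlap"


def _joint_vafs(a: "SNPProfile", b: "SNPProfile") -> tuple[np.ndarray, np.ndarray]:
    if a.reference_id != b.reference_id:
        raise ChainTraceError("profiles computed on different references")
    va, vb = [], []
    for name in a.positions:
        pa, pb = a.positions[name], b.positions.get(name, np.array([], dtype=int))
        common, ia, ib = np.intersect1d(pa, pb, return_indices=True)
        if len(common):
            va.append(a.vaf[name][ia])
            vb.append(b.vaf[name][ib])
    if not va:
        return np.array([]), np.array([])
    return np.concatenate(va), np.concatenate(vb)


def profile_distance(
    a: SNPProfile, b: SNPProfile, min_joint: int = 50
) -> tuple[float, int]:
    """Mean |VAF_a - VAF_b| over all jointly covered positions.

    Returns (distance, joint position count); the distance is NaN when the
    joint support is empty. Non-negative, symmetric, zero on identical
    profiles, and obeys the triangle inequality over a shared position set
    — a pseudometric on profiles sharing a reference. Note that averaging
    over the whole covered length dilutes a handful of fixed differences,
    which is why the same-strain verdict also counts high-frequency
    discordant positions (see :func:`same_strain`).
    """
    va, vb = _joint_vafs(a, b)
    if va.size == 0:
        return float("nan"), 0
    return float(np.mean(np.abs(va - vb))), int(va.size)


def discordant_positions(
    a: SNPProfile, b: SNPProfile, min_delta: float = 0.5
) -> int:
    """Jointly covered positions where the two VAFs differ by >= ``min_delta``.

    These are the "high-frequency SNP" disagreements that mark two samples
    as carrying different strains: positions where one sample is near-fixed
    for an allele the other essentially lacks.
    """
    va, vb = _joint_vafs(a, b)
    return int((np.abs(va - vb) >= min_delta).sum())


def same_strain(
    a: SNPProfile,
    b: SNPProfile,
    max_distance: float = 0.01,
    min_homogeneity: float = 0.95,
    min_joint: int = 50,
    major_threshold: float = 0.9,
    max_discordant: int = 10,
) -> IdentityDecision:
    """Same-strain verdict from distance, homogeneity, and discordance.

    Same strain requires (i) profile distance <= ``max_distance``, (ii)
    both samples' homogeneity (fraction of positions with a
    >= ``major_threshold`` major allele) >= ``min_homogeneity``, and (iii)
    fewer than ``max_discordant`` high-frequency discordant positions
    (|Δ VAF| >= 0.5). Too few jointly covered positions yields
    "insufficient-overlap" instead. The thresholds are calibration
    parameters validated on synthetic truth, not measured constants.
    """
    dist, joint = profile_distance(a, b, min_joint)
    n_disc = discordant_positions(a, b)
    ha, hb = a.homogeneity(major_threshold), b.homogeneity(major_threshold)
    if joint < min_joint:
        verdict = "insufficient-overlap"
    elif (
        dist <= max_distance
        and ha >= min_homogeneity
        and hb >= min_homogeneity
        and n_disc < max_discordant
    ):
        verdict = "same-strain"
    else:
        verdict = "different-strain"
    return IdentityDecision(
        distance=dist,
        homogeneity_a=ha,
        homogeneity_b=hb,
        joint_positions=joint,
        discordant_positions=n_disc,
        verdict=verdict,
    )


# ---------------------------------------------------------------------------
# average nucleotide identity
# ---------------------------------------------------------------------------


@dataclass
class ANIConfig:
    """Fragment-based ANI settings (the classic ~1 kb fragment convention)."""

    fragment_length: int = 1020
    min_identity: float = 0.30
    min_coverage: float = 0.70
    seed_k: int = 16
    seed_stride: int = 64
    max_candidates: int = 200

    def __post_init__(self) -> None:
        if self.fragment_length < 100:
            raise ConfigError("fragment_length must be >= 100")
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class ANIResult:
    ani: float  # percent
    forward_identity: float  # percent, query -> subject
    reverse_identity: float  # percent, subject -> query
    fragments_retained: tuple[int, int]
    fragments_total: tuple[int, int]


def _direction_identity(query: str, subject: str, config: ANIConfig) -> tuple[float, int, int]:
    """Mean retained-fragment identity (fraction) of query against subject."""
    sub_enc = {"+": encode(subject), "-": encode(revcomp(subject))}
    index = KmerIndex({"s": subject, "r": revcomp(subject)}, config.seed_k)
    strand_of = {"s": "+", "r": "-"}
    frags = [
        query[i : i + config.fragment_length]
        for i in range(0, len(query), config.fragment_length)
    ]
    frags = [f for f in frags if len(f) >= 100]
    identities = []
    retained = 0
    for frag in frags:
        L = len(frag)
        frag_enc = encode(frag)
        candidates: set[tuple[str, int]] = set()
        for off in range(0, max(1, L - config.seed_k + 1), config.seed_stride):
            seed = frag[off : off + config.seed_k]
            if len(seed) < config.seed_k or "N" in seed:
                continue
            for name, pos in index.lookup(seed):
                candidates.add((strand_of[name], pos - off))
            if len(candidates) >= config.max_candidates:
                break
        best_matches, best_alen = 0, 0
        for strand, offset in sorted(candidates):
            ref = sub_enc[strand]
            lo = max(0, offset)
            hi = min(ref.size, offset + L)
            if hi <= lo:
                continue
            window = ref[lo:hi]
            piece = frag_enc[lo - offset : hi - offset]
            matches = int(((window == piece) & (piece != 4)).sum())
            if matches > best_matches:
                best_matches, best_alen = matches, hi - lo
        if best_alen == 0:
            continue
        identity = best_matches / best_alen
        coverage = best_alen / L
        if identity >= config.min_identity and coverage >= config.min_coverage:
            identities.append(identity)
            retained += 1
    mean_id = float(np.mean(identities)) if identities else float("nan")
    return mean_id, retained, len(frags)


def ani(
    query: str | dict[str, str],
    subject: str | dict[str, str],
    config: ANIConfig | None = None,
) -> ANIResult:
    """Fragment-based average nucleotide identity between two genomes.

    The query is cut into consecutive fragments (default 1020 bp); each is
    placed at its best ungapped match in the subject, searching both
    strands by k-mer seeding; fragments aligning with identity >=
    ``min_identity`` over >= ``min_coverage`` of their length are retained;
    one direction's identity is the mean over retained fragments, and the
    reported ANI is the mean of both directions, in percent. Identical
    genomes give exactly 100.0.
    """
    config = config or ANIConfig()
    q = "".join(query.values()) if isinstance(query, dict) else query
    s = "".join(subject.values()) if isinstance(subject, dict) else subject
    if not q or not s:
        raise ChainTraceError("both genomes must be non-empty")
    fwd, ret_f, tot_f = _direction_identity(q, s, config)
    rev, ret_r, tot_r = _direction_identity(s, q, config)
    if ret_f == 0 or ret_r == 0:
        raise NoANISupportError(
            "no genome fragment passed the identity/coverage retention filters"
        )
    return ANIResult(
        ani=float((fwd + rev) / 2 * 100.0),
        forward_identity=float(fwd * 100.0),
        reverse_identity=float(rev * 100.0),
        fragments_retained=(ret_f, ret_r),
        fragments_total=(tot_f, tot_r),
    )
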