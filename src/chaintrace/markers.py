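"""Strain markers: contig filtering, primer design, in-silico PCR, and
strict (100%/100%) read mapping.

The tracing strategy: among the assembled contigs assigned to a species,
keep only those longer than 3000 bp (strict), use the largest as the strain
marker, design a primer pair on it that occurs nowhere in a background
sequence set (exact-substring specificity screen, a deterministic stand-in
for a database primer search), and call a strain present in a sample when
in-silico PCR yields an amplicon or when reads map to the marker at 100%
identity over 100% of their length.

Coordinates are 0-based half-open; strands are "+" / "-".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import KmerIndex, count_mismatches, encode, gc_fraction, revcomp, wallace_tm
from .errors import ChainTraceError, ConfigError, NoSpecificPrimerError


@dataclass(frozen=True)
class Contig:
    """One assembled sequence with its species assignment and origin."""

    id: str
    seq: str
    species: str | None = None
    sample: str | None = None

    @property
    def length(self) -> int:
        return len(self.seq)


def filter_contigs(contigs: list[Contig], min_len: int = 3000) -> list[Contig]:
    """Keep contigs strictly longer than ``min_len`` bp, preserving order.

    The default drops everything of 3000 bp or less, the retention rule
    used for reliable taxonomic assignment of assembled sequences.
    """
    return [c for c in contigs if c.length > min_len]


def select_marker_contig(contigs: list[Contig]) -> Contig:
    """The largest contig of a species; ties broken by smallest id."""
    if not contigs:
        raise ChainTraceError("no contigs to select a marker from")
    return min(contigs, key=lambda c: (-c.length, c.id))


# ---------------------------------------------------------------------------
# primer design
# ---------------------------------------------------------------------------


@dataclass
class PrimerConstraints:
    """Physical constraints on designed primers.

    Melting temperature uses the Wallace rule 2(A+T) + 4(G+C) — a crude but
    deterministic approximation adequate for in-silico screening.
    """

    primer_len: tuple[int, int] = (18, 25)
    product_len: tuple[int, int] = (100, 600)
    gc: tuple[float, float] = (0.40, 0.60)
    tm: tuple[float, float] = (50.0, 65.0)


@dataclass(frozen=True)
class Primer:
    seq: str
    start: int  # 0-based start of the annealing site on the marker + strand
    tm: float
    gc: float


@dataclass(frozen=True)
class StrainMarker:
    """A species marker contig plus its strain-specific primer pair."""

    species: str
    contig_id: str
    contig_seq: str
    forward: Primer
    reverse: Primer  # anneals on the - strand; seq is the primer as synthesized
    product_length: int
    background_screened: tuple[str, ...] = ()
    background_hits: int = 0


def _occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def _primer_ok(seq: str, constraints: PrimerConstraints) -> bool:
    if "N" in seq:
        return False
    g = gc_fraction(seq)
    if not constraints.gc[0] <= g <= constraints.gc[1]:
        return False
    t = wallace_tm(seq)
    return constraints.tm[0] <= t <= constraints.tm[1]


def design_primers(
    marker: Contig,
    background: list[str] | dict[str, str],
    constraints: PrimerConstraints | None = None,
) -> StrainMarker:
    """First constraint-satisfying primer pair specific against a background.

    Scans the marker left to right over forward-primer start positions,
    primer lengths, and product lengths (all ascending) and returns the
    first pair in which each primer occurs exactly once in the marker and
    neither primer nor its reverse complement occurs as an exact substring
    of any background sequence. Deterministic and invariant to background
    ordering (the screen is a set-membership test).
    """
    constraints = constraints or PrimerConstraints()
    if isinstance(background, dict):
        bg_ids = tuple(sorted(background))
        bg_seqs = [background[k] for k in bg_ids]
    else:
        bg_seqs = list(background)
        bg_ids = tuple(f"background_{i}" for i in range(len(bg_seqs)))
    # one joined text per orientation; '#' separators prevent junction matches
    bg_fwd = "#".join(bg_seqs)
    bg_rev = "#".join(revcomp(s) for s in bg_seqs)
    seq = marker.seq
    n = len(seq)
    min_pl, max_pl = constraints.primer_len
    min_prod, max_prod = constraints.product_len
    if n < min_prod:
        raise ConfigError(
            f"marker {marker.id!r} ({n} bp) shorter than the minimum product"
        )

    def specific(p: str) -> bool:
        return p not in bg_fwd and p not in bg_rev

    for fstart in range(0, n - min_prod + 1):
        for flen in range(min_pl, max_pl + 1):
            fwd = seq[fstart : fstart + flen]
            if len(fwd) < flen or not _primer_ok(fwd, constraints):
                continue
            if _occurrences(seq, fwd) != 1 or not specific(fwd):
                continue
            for prod in range(max(min_prod, flen + min_pl), max_prod + 1):
                end = fstart + prod
                if end > n:
                    break
                for rlen in range(min_pl, min(max_pl, prod - flen) + 1):
                    site = seq[end - rlen : end]
                    rev = revcomp(site)
                    if not _primer_ok(rev, constraints):
                        continue
                    if _occurrences(seq, site) != 1 or not specific(rev):
                        continue
                    return StrainMarker(
                        species=marker.species or "",
                        contig_id=marker.id,
                        contig_seq=seq,
                        forward=Primer(fwd, fstart, wallace_tm(fwd), gc_fraction(fwd)),
                        reverse=Primer(rev, end - rlen, wallace_tm(rev), gc_fraction(rev)),
                        product_length=prod,
                        background_screened=bg_ids,
                        background_hits=0,
                    )
    raise NoSpecificPrimerError(
        f"no specific primer pair on marker {marker.id!r}: the contig is not "
        f"strain-discriminative against the supplied background"
    )


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Amplicon:
    target_id: str
    start: int  # on the + strand of the target as given
    end: int  # half-open
    strand: str  # strand carrying the forward primer
    length: int


def in_silico_pcr(
    marker: StrainMarker,
    targets: dict[str, str],
    max_product: int | None = None,
) -> list[Amplicon]:
    """Exact-match PCR of the marker's primer pair against target sequences.

    An amplicon is reported wherever the forward primer matches a strand
    verbatim and the reverse primer's annealing site lies downstream within
    ``max_product`` bases. A single mismatch in either site suppresses the
    amplicon (exact-match semantics). No amplicon is simply a negative
    call, not an error.
    """
    if max_product is None:
        max_product = max(marker.product_length, 600)
    fwd = marker.forward.seq
    rev_site = revcomp(marker.reverse.seq)  # + strand annealing site
    out: list[Amplicon] = []
    for tid, seq in targets.items():
        for strand in "+-":
            text = seq if strand == "+" else revcomp(seq)
            start = 0
            while True:
                i = text.find(fwd, start)
                if i < 0:
                    break
                limit = min(len(text), i + max_product)
                j = text.find(rev_site, i + len(fwd), limit)
                while j >= 0:
                    end = j + len(rev_site)
                    if end - i > max_product:
                        break
                    if strand == "+":
                        a_start, a_end = i, end
                    else:
                        a_start, a_end = len(seq) - end, len(seq) - i
                    out.append(
                        Amplicon(
                            target_id=tid,
                            start=a_start,
                            end=a_end,
                            strand=strand,
                            length=end - i,
                        )
                    )
                    j = text.find(rev_site, j + 1, limit)
                start = i + 1
    return out


def pcr_presence(marker: StrainMarker, targets: dict[str, str]) -> bool:
    """Presence call from in-silico PCR: at least one amplicon."""
    return len(in_silico_pcr(marker, targets)) > 0


# ---------------------------------------------------------------------------
# strict read mapping
# ---------------------------------------------------------------------------


@dataclass
class MappingConfig:
    """Read-mapping presence rule. Defaults encode the strict 100%/100% cut-off."""

    identity_cutoff: float = 1.0
    coverage_cutoff: float = 1.0
    both_strands: bool = True
    min_reads_for_presence: int = 1
    min_breadth_for_presence: float = 0.5

    def __post_init__(self) -> None:
        for name in ("identity_cutoff", "coverage_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class ReadHit:
    read_id: str
    contig: str
    start: int  # 0-based on the contig + strand
    end: int  # half-open
    strand: str
    mismatches: int = 0


def _read_items(reads) -> list[tuple[str, str]]:
    if isinstance(reads, dict):
        return list(reads.items())
    out = []
    for r in reads:
        if hasattr(r, "read_id"):
            out.append((r.read_id, r.seq))
        else:
            rid, seq = r
            out.append((rid, seq))
    return out


def strict_map(
    reads,
    reference: list[Contig] | dict[str, str],
    config: MappingConfig | None = None,
) -> list[ReadHit]:
    """Exact full-length read placement on a contig set (all occurrences).

    With the default configuration a read hits wherever it, or its reverse
    complement, is an exact substring of a contig — a k-mer seed on the
    read's first bases followed by full verification, equivalent to naive
    substring search. Reads containing N never match. Reads longer than
    every contig are unmapped, not errors.

    An ``identity_cutoff`` below 1.0 delegates to the mismatch-tolerant
    engine (best unique placement, not all occurrences); a
    ``coverage_cutoff`` below 1.0 has no defined semantics for full-length
    ungapped alignment and is rejected.
    """
    config = config or MappingConfig()
    if config.coverage_cutoff < 1.0:
        raise ConfigError(
            "coverage_cutoff < 1.0 is not supported by the ungapped engines"
        )
    items = _read_items(reads)
    if not items:
        raise ChainTraceError("no reads given")
    seqs = (
        dict(reference)
        if isinstance(reference, dict)
        else {c.id: c.seq for c in reference}
    )
    if not seqs:
        raise ChainTraceError("empty reference")
    if config.identity_cutoff < 1.0:
        from .snp import tolerant_map  # local import to avoid a cycle

        return tolerant_map(
            items, seqs, max_mismatch_frac=1.0 - config.identity_cutoff
        )

    min_read = min(len(s) for _, s in items)
    k = min(31, min_read)
    index = KmerIndex(seqs, k)
    hits: list[ReadHit] = []
    for rid, seq in items:
        orientations = [("+", seq)]
        if config.both_strands:
            orientations.append(("-", revcomp(seq)))
        found = set()
        for strand, oriented in orientations:
            if "N" in oriented[:k]:
                continue
            for name, pos in index.lookup(oriented[:k]):
                ref = seqs[name]
                if ref[pos : pos + len(oriented)] == oriented and "N" not in oriented:
                    key = (name, pos, strand)
                    if key not in found:
                        found.add(key)
        for name, pos, strand in sorted(found):
            hits.append(
                ReadHit(
                    read_id=rid,
                    contig=name,
                    start=pos,
                    end=pos + len(seq),
                    strand=strand,
                    mismatches=0,
                )
            )
    return hits


def coverage_and_presence(
    hits: list[ReadHit],
    reference: list[Contig] | dict[str, str],
    config: MappingConfig | None = None,
) -> tuple[float, float, bool]:
    """Breadth, mean depth, and the presence verdict over a contig set.

    breadth = covered positions / total reference length;
    depth = aligned bases / total reference length;
    presence = (hits >= min_reads) and (breadth >= min_breadth).
    """
    config = config or MappingConfig()
    seqs = (
        dict(reference)
        if isinstance(reference, dict)
        else {c.id: c.seq for c in reference}
    )
    lengths = {name: len(s) for name, s in seqs.items()}
    total = sum(lengths.values())
    if total == 0:
        raise ChainTraceError("empty reference")
    covered = {name: np.zeros(n, dtype=bool) for name, n in lengths.items()}
    aligned_bases = 0
    for h in hits:
        if h.contig not in covered:
            raise ChainTraceError(f"hit on unknown contig {h.contig!r}")
        if h.end > lengths[h.contig]:
            raise ChainTraceError("hit extends past contig end; wrong reference?")
        covered[h.contig][h.start : h.end] = True
        aligned_bases += h.end - h.start
    breadth = sum(int(c.sum()) for c in covered.values()) / total
    depth = aligned_bases / total
    presence = (
        len(hits) >= config.min_reads_for_presence
        and breadth >= config.min_breadth_for_presence
    )
    return breadth, depth, presence
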