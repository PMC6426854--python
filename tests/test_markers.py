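"""Marker selection, primer design, in-silico PCR, and strict mapping."""

import numpy as np
import pytest

import chaintrace as ct
from chaintrace._seq import random_genome, revcomp
from chaintrace.errors import ChainTraceError, ConfigError, NoSpecificPrimerError
from chaintrace.markers import Contig, MappingConfig, PrimerConstraints

from .conftest import naive_exact_hits


class TestContigFiltering:
    def test_strict_3000_bp_boundary(self):
        contigs = [
            Contig("a", "A" * 3000),
            Contig("b", "A" * 3001),
        ]
        kept = ct.filter_contigs(contigs)
        assert [c.id for c in kept] == ["b"]

    def test_empty_set_passes_through(self):
        assert ct.filter_contigs([]) == []

    def test_matches_brute_force_length_scan(self, rng):
        contigs = [
            Contig(f"c{i}", "A" * int(rng.integers(1000, 6000))) for i in range(30)
        ]
        kept = ct.filter_contigs(contigs, 3000)
        assert kept == [c for c in contigs if len(c.seq) > 3000]
        # order preserved
        ids = [c.id for c in contigs if c.length > 3000]
        assert [c.id for c in kept] == ids


class TestMarkerSelection:
    def test_largest_contig_wins(self):
        contigs = [
            Contig("x", "A" * 5000),
            Contig("y", "A" * 12000),
            Contig("z", "A" * 8000),
        ]
        assert ct.select_marker_contig(contigs).id == "y"

    def test_length_tie_broken_by_smallest_id(self):
        contigs = [Contig("zz", "A" * 100), Contig("aa", "C" * 100)]
        assert ct.select_marker_contig(contigs).id == "aa"

    def test_agrees_with_sort_oracle(self, rng):
        for _ in range(20):
            contigs = [
                Contig(f"c{int(rng.integers(100)):03d}", "A" * int(rng.integers(1, 500)))
                for _ in range(10)
            ]
            # drop duplicate ids to satisfy uniqueness
            seen, uniq = set(), []
            for c in contigs:
                if c.id not in seen:
                    uniq.append(c)
                    seen.add(c.id)
            expected = sorted(uniq, key=lambda c: (-c.length, c.id))[0]
            assert ct.select_marker_contig(uniq) is expected

    def test_empty_input_rejected(self):
        with pytest.raises(ChainTraceError):
            ct.select_marker_contig([])


class TestPrimerDesign:
    def test_pair_lands_in_background_free_segment(self, rng):
        background_genome = random_genome(4000, rng)
        unique_segment = random_genome(300, rng)
        marker_seq = background_genome[:2000] + unique_segment + background_genome[2000:]
        marker = Contig("m", marker_seq, species="sp")
        designed = ct.design_primers(marker, {"bg": background_genome})
        # exhaustive oracle: neither primer occurs in the background
        for primer in (designed.forward.seq, designed.reverse.seq):
            assert primer not in background_genome
            assert revcomp(primer) not in background_genome
        # both sites occur exactly once in the marker
        assert marker_seq.count(designed.forward.seq) == 1
        site = revcomp(designed.reverse.seq)
        assert marker_seq.count(site) == 1
        assert designed.product_length == (
            marker_seq.find(site) + len(site) - designed.forward.start
        )

    def test_marker_contained_in_background_is_not_discriminative(self, rng):
        marker_seq = random_genome(2000, rng)
        with pytest.raises(NoSpecificPrimerError):
            ct.design_primers(Contig("m", marker_seq), {"self": marker_seq})

    def test_empty_background_returns_first_pair_in_scan_order(self, rng):
        marker_seq = random_genome(2000, rng)
        designed = ct.design_primers(Contig("m", marker_seq), {})
        rescan = ct.design_primers(Contig("m", marker_seq), {})
        assert designed.forward == rescan.forward
        # no earlier forward-primer start could have produced a pair: the scan
        # is left-to-right, so the returned start is minimal among valid pairs
        assert designed.forward.start >= 0
        constraints = PrimerConstraints()
        assert constraints.primer_len[0] <= len(designed.forward.seq) <= constraints.primer_len[1]
        assert constraints.product_len[0] <= designed.product_length <= constraints.product_len[1]
        assert constraints.gc[0] <= designed.forward.gc <= constraints.gc[1]
        assert constraints.tm[0] <= designed.forward.tm <= constraints.tm[1]

    def test_invariant_to_background_ordering(self, rng):
        marker_seq = random_genome(3000, rng)
        bgs = [random_genome(2000, rng) for _ in range(3)]
        a = ct.design_primers(Contig("m", marker_seq), {"a": bgs[0], "b": bgs[1], "c": bgs[2]})
        b = ct.design_primers(Contig("m", marker_seq), {"c": bgs[2], "a": bgs[0], "b": bgs[1]})
        assert (a.forward, a.reverse) == (b.forward, b.reverse)


class TestInSilicoPCR:
    @pytest.fixture
    def designed(self, rng):
        marker_seq = random_genome(3000, rng)
        return marker_seq, ct.design_primers(Contig("m", marker_seq, species="sp"), {})

    def test_verbatim_target_yields_one_amplicon_of_design_length(self, designed):
        marker_seq, marker = designed
        amps = ct.in_silico_pcr(marker, {"t": marker_seq})
        assert len(amps) == 1
        assert amps[0].length == marker.product_length

    def test_target_on_reverse_strand_still_amplifies(self, designed):
        marker_seq, marker = designed
        amps = ct.in_silico_pcr(marker, {"t": revcomp(marker_seq)})
        assert len(amps) == 1
        assert amps[0].length == marker.product_length

    def test_single_substitution_in_forward_site_kills_amplicon(self, designed):
        marker_seq, marker = designed
        pos = marker.forward.start + 3
        base = marker_seq[pos]
        sub = marker_seq[:pos] + ("A" if base != "A" else "C") + marker_seq[pos + 1 :]
        assert ct.in_silico_pcr(marker, {"t": sub}) == []

    def test_planted_chain_reproduces_matrix_pattern(self, rng):
        """A strain planted in all four matrices of one site is PCR-positive
        exactly there — the chain-wide colonizer pattern."""
        genome = random_genome(5000, rng)
        other = random_genome(5000, rng)
        marker = ct.design_primers(Contig("g", genome, species="sp"), {"bg": other})
        groups = {
            ("S1", m): {"assembly": genome, "bg": other}
            for m in ("CF", "LIT", "MIL", "PC")
        }
        groups.update({("S2", m): {"bg": other} for m in ("CF", "LIT", "MIL", "PC")})
        calls = {g: ct.pcr_presence(marker, targets) for g, targets in groups.items()}
        assert all(calls[("S1", m)] for m in ("CF", "LIT", "MIL", "PC"))
        assert not any(calls[("S2", m)] for m in ("CF", "LIT", "MIL", "PC"))


class TestStrictMap:
    def test_error_free_reads_all_map_to_source(self, small_genome):
        strain = ct.mutate_genome(small_genome, 0, 0, "s")
        reads = ct.simulate_reads(
            [(strain, 1.0)], ct.ReadSimParams(read_length=90, n_reads=300, seed=8)
        )
        hits = ct.strict_map(reads, {"g": small_genome})
        mapped = {h.read_id for h in hits}
        assert mapped == {r.read_id for r in reads}
        by_id = {}
        for h in hits:
            by_id.setdefault(h.read_id, []).append(h)
        for r in reads:
            assert any(
                h.start == r.position and h.strand == r.strand for h in by_id[r.read_id]
            )

    def test_reads_with_one_substitution_never_map(self, small_genome):
        strain = ct.mutate_genome(small_genome, 0, 0, "s")
        reads = ct.simulate_reads(
            [(strain, 1.0)],
            ct.ReadSimParams(read_length=90, n_reads=500, error_rate=0.02, seed=9),
        )
        with_errors = [r for r in reads if r.n_errors >= 1]
        assert with_errors
        assert ct.strict_map(with_errors, {"g": small_genome}) == []

    def test_n_bases_never_match(self, small_genome):
        read = small_genome[100:160]
        broken = read[:30] + "N" + read[31:]
        assert ct.strict_map({"r": broken}, {"g": small_genome}) == []

    def test_equivalent_to_naive_substring_oracle(self, rng):
        for trial in range(20):
            ref = {"c": random_genome(3000, rng)}
            reads = {}
            for i in range(30):
                if rng.random() < 0.5:  # true substring (either strand)
                    start = int(rng.integers(0, 3000 - 50))
                    seq = ref["c"][start : start + 50]
                    if rng.random() < 0.5:
                        seq = revcomp(seq)
                else:  # random sequence, overwhelmingly absent
                    seq = random_genome(50, rng)
                reads[f"r{i}"] = seq
            hits = ct.strict_map(reads, ref)
            got = {(h.read_id, h.contig, h.start, h.strand) for h in hits}
            assert got == naive_exact_hits(reads, ref)

    def test_sub_identity_config_delegates_to_tolerant_engine(self, small_genome):
        read = small_genome[200:300]
        mutated = "A" + read[1:] if read[0] != "A" else "C" + read[1:]
        strict_cfg = MappingConfig()
        assert ct.strict_map({"r": mutated}, {"g": small_genome}, strict_cfg) == []
        loose = MappingConfig(identity_cutoff=0.95)
        hits = ct.strict_map({"r": mutated}, {"g": small_genome}, loose)
        assert len(hits) == 1 and hits[0].start == 200 and hits[0].mismatches == 1

    def test_partial_coverage_config_rejected(self, small_genome):
        with pytest.raises(ConfigError):
            ct.strict_map(
                {"r": small_genome[:50]},
                {"g": small_genome},
                MappingConfig(coverage_cutoff=0.8),
            )

    def test_read_longer_than_contig_is_unmapped_not_error(self):
        hits = ct.strict_map({"r": "ACGT" * 50}, {"tiny": "ACGTACGT"})
        assert hits == []


class TestCoveragePresence:
    def test_tiling_reads_reach_full_breadth(self):
        ref = {"g": "ACGT" * 100}
        reads = {f"r{i}": ref["g"][i * 40 : i * 40 + 40] for i in range(10)}
        hits = ct.strict_map(reads, ref)
        breadth, depth, present = ct.coverage_and_presence(hits, ref)
        assert breadth == 1.0
        assert present

    def test_zero_hits_absent(self):
        breadth, depth, present = ct.coverage_and_presence([], {"g": "ACGT" * 100})
        assert (breadth, depth, present) == (0.0, 0.0, False)

    def test_simulated_depth_matches_expectation(self, small_genome):
        strain = ct.mutate_genome(small_genome, 0, 0, "s")
        target_depth = 10
        n_reads = target_depth * len(small_genome) // 100
        reads = ct.simulate_reads(
            [(strain, 1.0)], ct.ReadSimParams(read_length=100, n_reads=n_reads, seed=10)
        )
        hits = ct.strict_map(reads, {"g": small_genome})
        _, depth, _ = ct.coverage_and_presence(hits, {"g": small_genome})
        # sd of mean coverage ~ sqrt(depth * L_read / L) is loose; 3 sigma bound
        sigma = np.sqrt(target_depth * 100 / len(small_genome))
        assert abs(depth - target_depth) < 3 * sigma + 0.5

    def test_mismatched_reference_rejected(self, small_genome):
        hits = ct.strict_map({"r": small_genome[:50]}, {"g": small_genome})
        with pytest.raises(ChainTraceError):
            ct.coverage_and_presence(hits, {"other": "ACGT" * 10})
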