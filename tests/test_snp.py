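"""Tolerant mapping, pileups, SNP profiles, strain identity, and ANI."""

import numpy as np
import pytest

import chaintrace as ct
from chaintrace._seq import random_genome, revcomp
from chaintrace.errors import ChainTraceError, NoANISupportError
from chaintrace.snp import ANIConfig, SNPProfile

from .conftest import naive_exact_hits, naive_pileup


def _profile_from_reads(reads, ref, min_cov=5, frac=0.05):
    hits = ct.tolerant_map(reads, ref, max_mismatch_frac=frac)
    return ct.snp_profile(ct.pileup(hits, reads, ref), min_cov=min_cov)


def _make_profile(positions, vafs, ref_id=("r",)):
    pos = np.asarray(positions, dtype=int)
    vaf = np.asarray(vafs, dtype=float)
    return SNPProfile(
        reference_id=ref_id,
        positions={"r": pos},
        vaf={"r": vaf},
        major_freq={"r": np.maximum(vaf, 1 - vaf)},
        min_cov=5,
    )


class TestTolerantMap:
    def test_error_free_reads_match_strict_mapper(self, small_genome):
        strain = ct.mutate_genome(small_genome, 0, 0, "s")
        reads = ct.simulate_reads(
            [(strain, 1.0)], ct.ReadSimParams(read_length=100, n_reads=200, seed=12)
        )
        ref = {"g": small_genome}
        strict = {(h.read_id, h.contig, h.start, h.strand) for h in ct.strict_map(reads, ref)}
        tol = {(h.read_id, h.contig, h.start, h.strand) for h in ct.tolerant_map(reads, ref)}
        # random-genome reads place uniquely, so best-unique == all-occurrences
        assert tol == strict

    def test_single_substitution_reads_map_to_true_positions(self, small_genome):
        strain = ct.mutate_genome(small_genome, 0, 0, "s")
        reads = ct.simulate_reads(
            [(strain, 1.0)],
            ct.ReadSimParams(read_length=150, n_reads=300, error_rate=0.005, seed=13),
        )
        with_err = [r for r in reads if r.n_errors == 1]
        assert with_err
        hits = {h.read_id: h for h in ct.tolerant_map(with_err, {"g": small_genome})}
        for r in with_err:
            assert r.read_id in hits
            assert hits[r.read_id].start == r.position
            assert hits[r.read_id].strand == r.strand
            assert hits[r.read_id].mismatches == 1

    def test_repeated_locus_leaves_read_ambiguous(self, rng):
        unit = random_genome(200, rng)
        genome = unit + random_genome(500, rng) + unit
        read = unit[50:130]
        assert ct.tolerant_map({"r": read}, {"g": genome}) == []

    def test_mismatches_beyond_budget_leave_read_unmapped(self, small_genome):
        read = list(small_genome[100:200])
        for i in (5, 25, 45, 65, 85, 95):  # 6 substitutions on 100 bp, budget 5
            read[i] = "A" if read[i] != "A" else "C"
        assert ct.tolerant_map({"r": "".join(read)}, {"g": small_genome}) == []


class TestPileup:
    def test_identical_reads_stack_on_reference_base(self, small_genome):
        reads = {f"r{i}": small_genome[300:400] for i in range(10)}
        ref = {"g": small_genome}
        hits = ct.tolerant_map(reads, ref)
        pile = ct.pileup(hits, reads, ref)
        cov = pile.coverage("g")
        assert (cov[300:400] == 10).all()
        assert cov[:300].sum() == 0 and cov[400:].sum() == 0
        prof = ct.snp_profile(pile, min_cov=5)
        assert (prof.vaf["g"] == 0).all()

    def test_no_hits_gives_all_zero_pileup(self, small_genome):
        pile = ct.pileup([], {}, {"g": small_genome})
        assert pile.total_bases == 0

    def test_conservation_total_counts_equal_aligned_bases(self, small_genome):
        strain = ct.mutate_genome(small_genome, 0, 0, "s")
        reads = ct.simulate_reads(
            [(strain, 1.0)], ct.ReadSimParams(read_length=80, n_reads=100, seed=14)
        )
        ref = {"g": small_genome}
        hits = ct.tolerant_map(reads, ref)
        pile = ct.pileup(hits, reads, ref)
        assert pile.total_bases == sum(h.end - h.start for h in hits)

    def test_matches_naive_accumulation_oracle(self, rng):
        for _ in range(10):
            ref = {"c": random_genome(2000, rng)}
            reads = {}
            for i in range(40):
                start = int(rng.integers(0, 2000 - 60))
                seq = ref["c"][start : start + 60]
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                reads[f"r{i}"] = seq
            hits = ct.tolerant_map(reads, ref)
            pile = ct.pileup(hits, reads, ref)
            oracle = naive_pileup(hits, reads, ref)
            for bi, base in enumerate("ACGT"):
                assert (pile.counts["c"][bi] == np.array(oracle["c"][base])).all()


class TestSNPProfile:
    def test_low_coverage_positions_excluded(self, small_genome):
        reads = {f"r{i}": small_genome[0:50] for i in range(4)}
        ref = {"g": small_genome}
        hits = ct.tolerant_map(reads, ref)
        prof = ct.snp_profile(ct.pileup(hits, reads, ref), min_cov=5)
        assert prof.n_positions == 0

    def test_mixture_allele_frequency_recovered_within_3_sigma(self, rng):
        """70/30 reference/variant mixture: VAF at each planted SNP within
        binomial 3-sigma of 0.30 at ~50x coverage."""
        genome = random_genome(10_000, rng)
        ref_strain = ct.mutate_genome(genome, 0, 0, "ref")
        var_strain = ct.mutate_genome(genome, 100, 7, "var")
        n_reads = 50 * len(genome) // 100
        reads = ct.simulate_reads(
            [(ref_strain, 0.7), (var_strain, 0.3)],
            ct.ReadSimParams(read_length=100, n_reads=n_reads, seed=15),
        )
        ref = {"g": genome}
        prof = _profile_from_reads(reads, ref, min_cov=20)
        cov_map = dict(zip(prof.positions["g"], np.arange(prof.positions["g"].size)))
        hits = ct.tolerant_map(reads, ref)
        pile = ct.pileup(hits, reads, ref)
        cov = pile.coverage("g")
        vafs, ns, exceed = [], [], 0
        for pos, _, _ in var_strain.snps:
            if pos not in cov_map:
                continue
            vaf = prof.vaf["g"][cov_map[pos]]
            n = cov[pos]
            vafs.append(vaf)
            ns.append(n)
            if abs(vaf - 0.3) >= 3 * np.sqrt(0.3 * 0.7 / n):
                exceed += 1
        assert len(vafs) >= 80  # nearly all 100 planted positions evaluable
        # mean recovery within 3 sigma of the planted proportion, and no more
        # exceedances of the per-position 3-sigma band than chance allows
        # (P(>=3 of ~100) < 0.005 a priori)
        sigma_mean = np.sqrt(0.3 * 0.7 / sum(ns))
        assert abs(np.mean(vafs) - 0.3) < 3 * sigma_mean
        assert exceed <= 2


class TestProfileDistance:
    def test_identity_and_symmetry(self):
        a = _make_profile([1, 2, 3], [0.0, 0.5, 1.0])
        b = _make_profile([2, 3, 4], [0.0, 1.0, 0.2])
        da, _ = ct.profile_distance(a, a)
        assert da == 0.0
        dab, joint = ct.profile_distance(a, b)
        dba, _ = ct.profile_distance(b, a)
        assert joint == 2
        assert dab == pytest.approx(dba) == pytest.approx((0.5 + 0.0) / 2)

    def test_opposite_profiles_have_distance_one(self):
        a = _make_profile(range(10), [0.0] * 10)
        b = _make_profile(range(10), [1.0] * 10)
        d, _ = ct.profile_distance(a, b)
        assert d == 1.0

    def test_pseudometric_axioms_on_random_profiles(self, rng):
        positions = np.arange(100)
        for _ in range(50):
            profs = [
                _make_profile(positions, rng.random(100)) for _ in range(3)
            ]
            a, b, c = profs
            dab, _ = ct.profile_distance(a, b)
            dbc, _ = ct.profile_distance(b, c)
            dac, _ = ct.profile_distance(a, c)
            assert dab >= 0
            assert dab == pytest.approx(ct.profile_distance(b, a)[0])
            assert dac <= dab + dbc + 1e-12

    def test_different_references_rejected(self):
        a = _make_profile([1], [0.0], ref_id=("x",))
        b = _make_profile([1], [0.0], ref_id=("y",))
        with pytest.raises(ChainTraceError):
            ct.profile_distance(a, b)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(99)
    genome = random_genome(20_000, rng)
    same = ct.mutate_genome(genome, 0, 0, "same")
    other = ct.mutate_genome(genome, 50, 3, "other")
    ref = {"g": genome}
    n = 20 * len(genome) // 100  # ~20x
    mk = lambda strain, seed: _profile_from_reads(
        ct.simulate_reads(
            [(strain, 1.0)], ct.ReadSimParams(100, n, 0.0, seed)
        ),
        ref,
    )
    return mk(same, 31), mk(same, 32), mk(other, 33)


class TestSameStrain:
    def test_two_read_sets_of_one_strain_are_same_strain(self, planted):
        a, a2, _ = planted
        d = ct.same_strain(a, a2)
        assert d.verdict == "same-strain"
        assert d.discordant_positions == 0
        assert d.distance == pytest.approx(0.0, abs=1e-9)

    def test_fifty_snp_variant_is_different_strain(self, planted):
        a, _, b = planted
        d = ct.same_strain(a, b)
        assert d.verdict == "different-strain"
        # the planted 50 fixed differences surface as high-frequency discordance
        assert d.discordant_positions >= 40
        within, _ = ct.profile_distance(a, planted[1])
        between = d.distance
        assert within < between

    def test_no_joint_positions_is_insufficient_overlap(self):
        a = _make_profile([1, 2], [0.0, 0.0])
        b = _make_profile([10, 11], [0.0, 0.0])
        assert ct.same_strain(a, b).verdict == "insufficient-overlap"


class TestANI:
    def test_identical_genomes_give_exactly_100(self, rng):
        g = random_genome(60_000, rng)
        res = ct.ani(g, g)
        assert res.ani == 100.0
        assert res.fragments_retained == res.fragments_total

    def test_reverse_complement_gives_100(self, rng):
        g = random_genome(30_000, rng)
        assert ct.ani(g, revcomp(g)).ani == 100.0

    def test_one_percent_substitution_gives_ani_near_99(self, rng):
        g = random_genome(50_000, rng)
        mutated = ct.mutate_genome(g, 500, 21, "m").genome
        res = ct.ani(g, mutated)
        assert abs(res.ani - 99.0) < 0.2

    def test_monotone_in_substitution_rate(self, rng):
        g = random_genome(40_000, rng)
        rates = [0, 200, 400, 800]  # 0, 0.5%, 1%, 2%
        anis = [
            ct.ani(g, ct.mutate_genome(g, n, 5, "m").genome).ani for n in rates
        ]
        assert anis[0] == 100.0
        assert all(a >= b for a, b in zip(anis, anis[1:]))

    def test_unrelated_genomes_have_no_support(self, rng):
        with pytest.raises(NoANISupportError):
            ct.ani(random_genome(20_000, rng), random_genome(20_000, rng))

    def test_fragment_length_below_100_rejected(self):
        from chaintrace.errors import ConfigError

        with pytest.raises(ConfigError):
            ANIConfig(fragment_length=50)
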