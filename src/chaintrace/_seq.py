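"""Low-level nucleotide sequence helpers shared across modules.

Sequences are plain upper-case strings over A/C/G/T (plus N, which never
matches anything in the exact or mismatch-tolerant engines). Numeric work
encodes bases as uint8: A=0, C=1, G=2, T=3, N/other=4.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return "".join("ACGTN"[b] for b in arr)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def wallace_tm(seq: str) -> float:
    """Melting temperature by the Wallace rule: 2(A+T) + 4(G+C) degrees C."""
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


def random_genome(length: int, rng: np.random.Generator) -> str:
    """Uniform random A/C/G/T genome of the given length."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


class KmerIndex:
    """Exact k-mer index over a set of named sequences.

    Maps every k-mer (as a string) to a list of (sequence name, start)
    pairs. k-mers containing N are not indexed, so reads carrying N can
    never seed a match.
    """

    def __init__(self, sequences: dict[str, str], k: int):
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.sequences = dict(sequences)
        self._encoded = {name: encode(s) for name, s in self.sequences.items()}
        index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((name, i))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])

    def encoded(self, name: str) -> np.ndarray:
        return self._encoded[name]

    def length(self, name: str) -> int:
        return len(self.sequences[name])


def count_mismatches(ref_arr: np.ndarray, read_arr: np.ndarray, start: int) -> int:
    """Mismatches of an ungapped full-length placement of read at ``start``.

    Returns a large sentinel if the placement runs off either end. N (code 4)
    never matches, including N-vs-N.
    """
    end = start + read_arr.size
    if start < 0 or end > ref_arr.size:
        return read_arr.size + 1
    window = ref_arr[start:end]
    matches = (window == read_arr) & (read_arr != 4)
    return int(read_arr.size - matches.sum())
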