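"""Small DNA sequence utilities shared across modules.

Coordinates are 0-based, half-open everywhere in the library; conversion to
the 1-based numbering used in human-facing reports happens in one place
(:func:`shapecov.io.to_report_position`).
"""

from __future__ import annotations

from itertools import product

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: IUPAC degenerate nucleotide codes used in consensus patterns.
IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "N": frozenset("ACGT"),
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographically smaller of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def check_acgt(seq: str, context: str = "sequence") -> None:
    bad = set(seq) - set(DNA_BASES)
    if bad:
        raise ValueError(
            f"{context} contains characters outside A/C/G/T: {sorted(bad)!r} "
            "(expand or reject ambiguity codes before calling)"
        )


def matches_pattern(seq: str, pattern: str) -> bool:
    """True if ``seq`` matches an IUPAC consensus ``pattern`` of equal length."""
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC[p] for b, p in zip(seq, pattern))


def all_kmers(k: int):
    """Iterate all 4**k DNA k-mers in lexicographic order."""
    for tup in product(DNA_BASES, repeat=k):
        yield "".join(tup)


def canonical_kmers(k: int) -> list[str]:
    """All k-mers collapsed to one representative per revcomp pair."""
    return sorted({canonical(m) for m in all_kmers(k)})


def encode(seq: str) -> list[int]:
    """Map A,C,G,T -> 0,1,2,3."""
    return [DNA_BASES.index(b) for b in seq]


def pentamer_index(seq: str) -> int:
    """Base-4 integer id of a pentamer (A=0..T=3, first base most significant)."""
    idx = 0
    for b in seq:
        idx = idx * 4 + DNA_BASES.index(b)
    return idx
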