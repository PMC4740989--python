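"""Small sequence helpers used by several modules.

Exact, strand-agnostic substring matching deliberately replaces the
BLAST searches used on real data: for 100 %-identity hits of probes
>= 24 nt the two criteria coincide, and exact matching is deterministic
and dependency-free.
"""

from __future__ import annotations

from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


def find_all(haystack: str, needle: str) -> list[int]:
    """All 0-based start positions of exact occurrences of needle."""
    hits = []
    start = haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def translate(seq: str) -> str:
    """Translate a nucleotide string (trimmed to codon length)."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())
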