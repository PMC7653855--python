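"""Inverted-repeat detection in promoter-scale DNA sequence.

An inverted repeat is a k-mer whose reverse complement occurs again
downstream; such pairs are candidate binding sites for unknown regulators
or cruciform-forming elements, and are the natural hypothesis when a
promoter deletion changes expression of the downstream gene.
"""

from __future__ import annotations

__all__ = ["reverse_complement", "find_inverted_repeats"]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def find_inverted_repeats(
    sequence: str, k: int, max_gap: int | None = None, ignore_ambiguous: bool = False
) -> list[tuple[int, int, str]]:
    """All (pos1, pos2, motif) with revcomp(motif at pos1) at pos2 > pos1.

    Positions are 0-based.  The gap is ``pos2 - (pos1 + k)`` (negative for
    overlapping arms) and is limited to ``max_gap`` when given.  Ambiguous
    bases raise unless ``ignore_ambiguous`` is set, in which case k-mers
    containing them are skipped.
    """
    if k < 2:
        raise ValueError("motif length k must be >= 2")
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad and not ignore_ambiguous:
        raise ValueError(f"ambiguous bases in sequence: {sorted(bad)}")

    positions: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if set(kmer) <= _VALID:
            positions.setdefault(kmer, []).append(i)

    hits: list[tuple[int, int, str]] = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if not set(kmer) <= _VALID:
            continue
        for j in positions.get(reverse_complement(kmer), ()):
            if j <= i:
                continue
            if max_gap is not None and j - (i + k) > max_gap:
                continue
            hits.append((i, j, kmer))
    hits.sort()
    return hits
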