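"""Sequence algebra for four-base 5' overhangs.

A cohesive end ("overhang") is the four-nucleotide single-stranded 5'
extension left by a Type IIS restriction digest; two ends anneal in
antiparallel orientation, so position ``i`` of the top-strand overhang
opposes position ``5 - i`` of the bottom-strand overhang (N1:N4, N2:N3,
N3:N2, N4:N1).  All sequences are written 5'->3' on their own strand and
positions are 1-based within the overhang (N1..N4).

The module provides complements, the Watson-Crick pairing test, mismatch
enumeration with the edge/middle position classification, GC content, and
simple N-wildcard pattern matching, plus the vectorised pairing tables
(mismatch masks over all 256 x 256 ordered pairs) used by the simulator
and the profiler.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

ALPHABET = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_RC_TABLE = str.maketrans("ACGT", "TGCA")

OVERHANG_LENGTH = 4

#: All 256 four-base overhangs in lexicographic order.
OVERHANGS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(ALPHABET, repeat=OVERHANG_LENGTH)
)
OVERHANG_INDEX: dict[str, int] = {o: i for i, o in enumerate(OVERHANGS)}

EDGE_POSITIONS = (1, 4)
MIDDLE_POSITIONS = (2, 3)


class SequenceError(ValueError):
    """Raised for sequences outside the strict A/C/G/T assay alphabet."""


def clean_dna(seq: str, *, name: str = "sequence", length: int | None = None) -> str:
    """Validate a DNA string against the strict ACGT alphabet.

    Lowercase input is normalised to uppercase with a warning; U and IUPAC
    ambiguity codes are rejected.  If ``length`` is given the sequence must
    have exactly that length.
    """
    if not isinstance(seq, str):
        raise SequenceError(f"{name} must be a string, got {type(seq).__name__}")
    if seq != seq.upper():
        warnings.warn(f"{name} {seq!r} contains lowercase; normalising to uppercase")
        seq = seq.upper()
    if length is not None and len(seq) != length:
        raise SequenceError(f"{name} must have length {length}, got {seq!r}")
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise SequenceError(
            f"{name} {seq!r} contains characters outside ACGT: {sorted(bad)}"
        )
    return seq


def clean_overhang(seq: str) -> str:
    """Validate a four-base overhang (strict ACGT, length 4)."""
    return clean_dna(seq, name="overhang", length=OVERHANG_LENGTH)


def reverse_complement(o: str) -> str:
    """Watson-Crick partner of an overhang, read 5'->3' on its own strand.

    An involution: ``reverse_complement(reverse_complement(o)) == o``.
    """
    return clean_overhang(o)[::-1].translate(_RC_TABLE)


def is_palindrome(o: str) -> bool:
    """True iff the overhang is its own Watson-Crick partner (e.g. ACGT)."""
    return reverse_complement(o) == o


#: The 16 palindromic overhangs, which ligate correctly to themselves.
PALINDROMES: tuple[str, ...] = tuple(o for o in OVERHANGS if is_palindrome(o))


def is_watson_crick(top: str, bottom: str) -> bool:
    """True iff the ordered pair (top, bottom) is fully complementary.

    Symmetric in top/bottom because reverse complementation is an
    involution.
    """
    return reverse_complement(top) == clean_overhang(bottom)


def position_class(position_index: int) -> str:
    """'edge' for junction-terminal positions 1 and 4, 'middle' for 2 and 3."""
    if position_index in EDGE_POSITIONS:
        return "edge"
    if position_index in MIDDLE_POSITIONS:
        return "middle"
    raise ValueError(f"position_index must be 1..4, got {position_index}")


def canonical_pair_label(a: str, b: str) -> str:
    """Unordered base-pair type label, e.g. both T:G and G:T -> 'G:T'."""
    x, y = sorted((a, b))
    return f"{x}:{y}"


@dataclass(frozen=True)
class MismatchRecord:
    """A non-Watson-Crick opposing base pair at one junction position.

    ``position_index`` is 1-based on the top strand; the opposing bottom
    base sits at position ``5 - position_index`` of the bottom strand.
    """

    position_index: int
    position_class: str
    top_base: str
    bottom_base: str

    @property
    def label(self) -> str:
        """Oriented label 'top:bottom', e.g. 'T:G'."""
        return f"{self.top_base}:{self.bottom_base}"

    @property
    def pair_type(self) -> str:
        """Canonical unordered label, e.g. 'G:T' for both T:G and G:T."""
        return canonical_pair_label(self.top_base, self.bottom_base)


def mismatches(top: str, bottom: str) -> tuple[MismatchRecord, ...]:
    """Enumerate mismatched opposing base pairs of an ordered overhang pair.

    Returns one record per position whose opposing bases are not
    complementary; empty iff the pair is Watson-Crick.  The result for
    (bottom, top) maps onto this one by position_index i <-> 5 - i with the
    bases swapped.
    """
    top = clean_overhang(top)
    bottom = clean_overhang(bottom)
    records = []
    for pos in range(1, OVERHANG_LENGTH + 1):
        t = top[pos - 1]
        b = bottom[OVERHANG_LENGTH - pos]
        if COMPLEMENT[t] != b:
            records.append(MismatchRecord(pos, position_class(pos), t, b))
    return tuple(records)


def gc_count(o: str) -> int:
    """Number of G or C bases in the overhang (0..4)."""
    o = clean_overhang(o)
    return sum(c in "GC" for c in o)


def gc_percent(o: str) -> int:
    """GC content as a percentage, one of {0, 25, 50, 75, 100}."""
    return gc_count(o) * 25


def matches_pattern(o: str, pattern: str) -> bool:
    """Positionwise match of an overhang against an ACGTN pattern.

    ``N`` matches any base; e.g. 'TGGA' matches 'TNNA'.
    """
    o = clean_overhang(o)
    if not isinstance(pattern, str) or len(pattern) != OVERHANG_LENGTH:
        raise SequenceError(f"pattern must be a 4-character string, got {pattern!r}")
    bad = set(pattern) - set(ALPHABET + "N")
    if bad:
        raise SequenceError(f"pattern {pattern!r} contains invalid characters: {sorted(bad)}")
    return all(p == "N" or p == c for p, c in zip(pattern, o))


# ---------------------------------------------------------------------------
# Vectorised pairing tables over all 256 x 256 ordered pairs.
#
# Entry [i, j] of each table refers to the ordered pair
# (top = OVERHANGS[i], bottom = OVERHANGS[j]).

#: Base codes (A=0, C=1, G=2, T=3) per overhang position, shape (256, 4).
CODES: np.ndarray = np.array(
    [[ALPHABET.index(c) for c in o] for o in OVERHANGS], dtype=np.int8
)

#: Complement under the A/C/G/T coding: A<->T, C<->G.
COMP_CODE: np.ndarray = np.array([3, 2, 1, 0], dtype=np.int8)

#: Index of each overhang's reverse complement.
RC_INDEX: np.ndarray = np.array(
    [OVERHANG_INDEX[reverse_complement(o)] for o in OVERHANGS]
)

#: GC count per overhang, shape (256,).
GC_COUNTS: np.ndarray = np.array([gc_count(o) for o in OVERHANGS], dtype=np.int8)


def _build_tables():
    masks = np.empty((OVERHANG_LENGTH, 256, 256), dtype=bool)
    gc_pairs = np.zeros((256, 256), dtype=np.int8)
    for pos in range(1, OVERHANG_LENGTH + 1):
        top_code = CODES[:, pos - 1]
        opp_code = CODES[:, OVERHANG_LENGTH - pos]
        mism = COMP_CODE[top_code][:, None] != opp_code[None, :]
        masks[pos - 1] = mism
        # a matched G or C on the top strand is one annealed G:C pair
        is_gc = np.isin(top_code, [1, 2])
        gc_pairs += (~mism) & is_gc[:, None]
    return masks, gc_pairs


#: [pos-1, i, j] True iff top position pos of pair (i, j) is mismatched.
MISMATCH_MASKS: np.ndarray
#: Number of correctly annealed G:C base pairs per ordered pair.
GC_PAIR_COUNTS: np.ndarray
MISMATCH_MASKS, GC_PAIR_COUNTS = _build_tables()

#: Mismatch count (0..4) per ordered pair.
N_MISMATCHES: np.ndarray = MISMATCH_MASKS.sum(axis=0, dtype=np.int8)

#: True iff the ordered pair is Watson-Crick.
WC_MASK: np.ndarray = N_MISMATCHES == 0

#: True iff the pair has >=1 mismatch at an edge position (1 or 4).
EDGE_MISMATCH_MASK: np.ndarray = MISMATCH_MASKS[0] | MISMATCH_MASKS[3]
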