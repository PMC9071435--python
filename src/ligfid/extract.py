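"""Overhang-pair extraction and dual-orientation count tabulation.

Turns ligation-product strand reads (or supplied CSV count tables) into a
validated 256 x 256 pair-count matrix.  Because strand designation of a
ligation product is arbitrary, every product is counted in both
orientations (top-to-bottom and bottom-to-top), which makes the matrix
symmetric and the total ordered count exactly twice the number of
products; a palindromic self-ligation contributes 2 to its diagonal cell.
All downstream statistics use ordered counts, so product-level and
event-level fractions coincide.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import overhangs as oh
from .overhangs import ALPHABET, OVERHANGS, OVERHANG_INDEX
from .simulate import ProductRecord, SubstrateSpec

FAILURE_REASONS = ("anchor-missing", "wrong-gap-length", "non-ACGT")


@dataclass
class PairCountMatrix:
    """Dual-orientation overhang pair counts for one sample or condition.

    ``counts[i, j]`` is the number of ordered observations with top
    overhang ``OVERHANGS[i]`` and bottom overhang ``OVERHANGS[j]``.
    ``control_tallies`` (optional) holds per-position base counts of the
    control hexamers seen during extraction, shape (control_len, 4) in
    A/C/G/T order.
    """

    counts: np.ndarray
    metadata: dict = field(default_factory=dict)
    control_tallies: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (256, 256):
            raise ValueError(f"counts must be 256x256, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total_ordered(self) -> int:
        return int(self.counts.sum())

    @property
    def n_products(self) -> int:
        return self.total_ordered // 2

    @property
    def is_symmetric(self) -> bool:
        return bool((self.counts == self.counts.T).all())

    def symmetrize(self) -> "PairCountMatrix":
        """Return the dual-orientation form of a single-orientation matrix."""
        return PairCountMatrix(
            counts=self.counts + self.counts.T,
            metadata=dict(self.metadata),
            control_tallies=self.control_tallies,
        )


@dataclass(frozen=True)
class Observation:
    """One successfully parsed ligation product."""

    top: str
    bottom: str
    controls: tuple[str | None, str | None] = (None, None)


@dataclass(frozen=True)
class ExtractionFailure:
    """A read pair that could not be parsed; never silently dropped."""

    reason: str
    detail: str = ""


@dataclass
class ExtractionLog:
    n_products: int = 0
    failures: Counter = field(default_factory=Counter)

    @property
    def n_failed(self) -> int:
        return sum(self.failures.values())

    @property
    def failure_fraction(self) -> float:
        total = self.n_products + self.n_failed
        return self.n_failed / total if total else 0.0


def _hamming_find(read: str, anchor: str, start: int = 0) -> int:
    """Leftmost position >= start where anchor matches with <=1 substitution."""
    best = -1
    for i in range(start, len(read) - len(anchor) + 1):
        mis = sum(a != b for a, b in zip(read[i:i + len(anchor)], anchor))
        if mis <= 1:
            return i
    return best


def _extract_strand(read: str, spec: SubstrateSpec, fuzzy: bool):
    left = spec.left_const
    right = spec.right_anchor
    i = read.find(left)
    if i < 0 and fuzzy:
        i = _hamming_find(read, left)
    if i < 0:
        return ExtractionFailure("anchor-missing", "left anchor not found")
    after_left = i + len(left)
    j = read.find(right, after_left)
    if j < 0 and fuzzy:
        j = _hamming_find(read, right, after_left)
    if j < 0:
        return ExtractionFailure("anchor-missing", "right anchor not found")
    gap = j - after_left
    if gap != oh.OVERHANG_LENGTH:
        return ExtractionFailure("wrong-gap-length", f"gap of {gap} between anchors")
    overhang = read[after_left:j]
    if set(overhang) - set(ALPHABET):
        return ExtractionFailure("non-ACGT", f"overhang {overhang!r}")
    cstart = j + len(right)
    control = read[cstart:cstart + spec.control_len]
    if len(control) != spec.control_len or set(control) - set(ALPHABET):
        control = None
    return overhang, control


def parse_product(
    top_read: str,
    bottom_read: str,
    spec: SubstrateSpec | None = None,
    fuzzy: bool = False,
):
    """Extract the overhang pair and control hexamers from one product.

    Anchors are located by exact match (consensus reads are high-accuracy;
    a mismatched anchor marks an unusable read); ``fuzzy=True`` additionally
    allows one substitution per anchor.  Returns an :class:`Observation` or
    an :class:`ExtractionFailure` with a reason code.
    """
    if spec is None:
        spec = SubstrateSpec()
    if not top_read or not bottom_read:
        return ExtractionFailure("anchor-missing", "empty read")
    results = []
    for read in (top_read, bottom_read):
        res = _extract_strand(read.upper(), spec, fuzzy)
        if isinstance(res, ExtractionFailure):
            return res
        results.append(res)
    (top, ctrl_top), (bottom, ctrl_bottom) = results
    return Observation(top=top, bottom=bottom, controls=(ctrl_top, ctrl_bottom))


def tabulate(
    observations: Iterable[Observation],
    metadata: dict | None = None,
    control_len: int = 6,
) -> PairCountMatrix:
    """Count observations in both orientations into a pair-count matrix.

    Each product increments ``counts[top][bottom]`` and
    ``counts[bottom][top]``; a palindromic self-pair therefore adds 2 to its
    diagonal cell.  Control hexamers, when present, are tallied per position
    for the synthesis-bias correction.
    """
    counts = np.zeros((256, 256), dtype=np.int64)
    tallies = np.zeros((control_len, 4), dtype=np.int64)
    saw_controls = False
    for obs in observations:
        i = OVERHANG_INDEX[obs.top]
        j = OVERHANG_INDEX[obs.bottom]
        counts[i, j] += 1
        counts[j, i] += 1
        for control in obs.controls:
            if control is not None and len(control) == control_len:
                saw_controls = True
                for pos, base in enumerate(control):
                    tallies[pos, ALPHABET.index(base)] += 1
    return PairCountMatrix(
        counts=counts,
        metadata=dict(metadata or {}),
        control_tallies=tallies if saw_controls else None,
    )


def extract_products(
    products: Iterable[ProductRecord],
    spec: SubstrateSpec | None = None,
    fuzzy: bool = False,
    metadata: dict | None = None,
) -> tuple[PairCountMatrix, ExtractionLog]:
    """Parse and tabulate a stream of product records, logging failures."""
    if spec is None:
        spec = SubstrateSpec()
    log = ExtractionLog()

    def gen():
        for rec in products:
            res = parse_product(rec.top_strand, rec.bottom_strand, spec, fuzzy)
            if isinstance(res, ExtractionFailure):
                log.failures[res.reason] += 1
            else:
                log.n_products += 1
                yield res

    matrix = tabulate(gen(), metadata=metadata, control_len=spec.control_len)
    return matrix, log


def iter_fasta_products(path) -> Iterator[ProductRecord]:
    """Pair FASTA/FASTQ records by the ``#top`` / ``#bottom`` ID suffix."""
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    pending: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), fmt):
        name, _, strand = rec.id.rpartition("#")
        if strand not in ("top", "bottom") or not name:
            raise ValueError(f"record id {rec.id!r} lacks a #top/#bottom suffix")
        entry = pending.setdefault(name, {})
        entry[strand] = str(rec.seq)
        if len(entry) == 2:
            del pending[name]
            yield ProductRecord(name, entry["top"], entry["bottom"])
    if pending:
        warnings.warn(f"{len(pending)} unpaired record(s) ignored: {sorted(pending)[:5]}")


def combine_replicates(
    matrices: list[PairCountMatrix], override: bool = False
) -> PairCountMatrix:
    """Elementwise sum of replicate count matrices.

    Replicates of the same (ligase, condition) are combined before any
    statistic is computed.  Mismatched condition metadata raises unless
    ``override=True``.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    keys = ("ligase", "condition")
    reference = {k: matrices[0].metadata.get(k) for k in keys}
    for m in matrices[1:]:
        current = {k: m.metadata.get(k) for k in keys}
        if current != reference and not override:
            raise ValueError(
                f"replicate condition mismatch: {current} != {reference} "
                "(pass override=True to combine anyway)"
            )
    counts = sum(m.counts for m in matrices)
    tallies = [m.control_tallies for m in matrices if m.control_tallies is not None]
    replicates = []
    for m in matrices:
        replicates.extend(m.metadata.get("replicates", []) or [m.metadata.get("sample", "?")])
    meta = dict(matrices[0].metadata)
    meta["replicates"] = replicates
    return PairCountMatrix(
        counts=counts,
        metadata=meta,
        control_tallies=sum(tallies) if tallies else None,
    )


# ---------------------------------------------------------------------------
# Counts CSV I/O.
#
# Long form: header `top_overhang,bottom_overhang,count`, one row per
# nonzero cell.  Wide form: 256 x 256 table with overhang row/column labels.
# The reader autodetects the dialect and tolerates a header line.

def write_counts_csv(matrix: PairCountMatrix, path) -> None:
    """Write the matrix in long form (lossless: write then read is identity)."""
    i, j = np.nonzero(matrix.counts)
    frame = pd.DataFrame(
        {
            "top_overhang": [OVERHANGS[a] for a in i],
            "bottom_overhang": [OVERHANGS[b] for b in j],
            "count": matrix.counts[i, j],
        }
    )
    frame.to_csv(path, index=False)


def _check_overhang(value, row: int, column: str) -> int:
    value = str(value).strip().upper()
    idx = OVERHANG_INDEX.get(value)
    if idx is None:
        raise ValueError(f"row {row}: invalid {column} overhang {value!r}")
    return idx


def read_counts_csv(path, symmetrize: bool = False) -> PairCountMatrix:
    """Read a counts CSV in long or wide form (autodetected).

    Non-symmetric input is accepted but flagged with a warning; it is
    symmetrized only when ``symmetrize=True`` is requested explicitly.
    """
    frame = pd.read_csv(path)
    columns = [str(c).strip().lower() for c in frame.columns]
    counts = np.zeros((256, 256), dtype=np.int64)
    if {"top_overhang", "bottom_overhang", "count"} <= set(columns):
        frame.columns = columns
        for row, rec in enumerate(frame.itertuples(index=False), start=2):
            i = _check_overhang(rec.top_overhang, row, "top")
            j = _check_overhang(rec.bottom_overhang, row, "bottom")
            try:
                value = int(rec.count)
            except (TypeError, ValueError):
                raise ValueError(f"row {row}: count {rec.count!r} is not an integer")
            if value < 0:
                raise ValueError(f"row {row}: negative count {value}")
            counts[i, j] += value
    else:
        # wide form: first column holds the top overhang labels
        frame = pd.read_csv(path, index_col=0)
        if frame.shape != (256, 256):
            raise ValueError(
                f"{path}: not a long-form counts CSV and not 256x256 "
                f"(got {frame.shape})"
            )
        rows = [_check_overhang(v, k + 2, "row") for k, v in enumerate(frame.index)]
        cols = [_check_overhang(v, 1, "column") for v in frame.columns]
        values = frame.to_numpy()
        if (values < 0).any():
            raise ValueError(f"{path}: negative counts in wide-form table")
        counts[np.ix_(rows, cols)] = values.astype(np.int64)
    matrix = PairCountMatrix(counts=counts, metadata={"sample": str(path)})
    if not matrix.is_symmetric:
        if symmetrize:
            matrix = matrix.symmetrize()
        else:
            warnings.warn(
                f"{path}: counts are not symmetric (single-orientation table?); "
                "pass symmetrize=True to fold orientations"
            )
    return matrix
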