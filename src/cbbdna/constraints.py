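"""Biochemical constraint predicates and the scalar sequence error.

Synthesis and sequencing quality degrade for oligos whose GC fraction
drifts away from 50% (C1) or that contain long homopolymer runs (C2);
cross-hybridization noise additionally requires low mutual similarity
among barcodes, payloads and whole oligos (C3-C5, audited via
:mod:`cbbdna.lsh`). This module provides the C1/C2 predicates and the
error functional used to rank candidate permutations of a sequence:

    error(s) = w_gc * |gc(s) - 1/2|
             + w_hp * (sum over maximal runs longer than H of (run - H)) / |s|

which is zero exactly when the GC content is 50% and no run exceeds the
homopolymer bound H, and grows monotonically in both defect types.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import DnaAlphabetError, EmptySequenceError

DNA_ALPHABET = "ACGT"
_DNA_SET = frozenset(DNA_ALPHABET)
_RUN_RE = re.compile(r"(.)\1*")


def validate_dna(seq: str) -> str:
    """Return *seq* unchanged if it is a canonical uppercase DNA string."""
    if not _DNA_SET.issuperset(seq):
        bad = sorted(set(seq) - _DNA_SET)
        raise DnaAlphabetError(f"non-ACGT characters in sequence: {bad}")
    return seq


@dataclass(frozen=True)
class ConstraintThresholds:
    """Numeric bounds for C1 (GC window), C2 (homopolymers) and C3/C5
    (maximum tolerated pairwise Jaccard similarity)."""

    gc_low: float = 0.4
    gc_high: float = 0.6
    max_homopolymer: int = 3
    max_similarity: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.gc_low <= 0.5 <= self.gc_high <= 1.0):
            raise ValueError("require 0 <= gc_low <= 0.5 <= gc_high <= 1")
        if self.max_homopolymer < 1:
            raise ValueError("max_homopolymer must be >= 1")
        if not (0.0 <= self.max_similarity <= 1.0):
            raise ValueError("max_similarity must lie in [0, 1]")


# Fully permissive bounds: every sequence passes C1/C2.
LAX_THRESHOLDS = ConstraintThresholds(
    gc_low=0.0, gc_high=1.0, max_homopolymer=10**9, max_similarity=1.0
)


@dataclass(frozen=True)
class ErrorWeights:
    w_gc: float = 1.0
    w_hp: float = 1.0

    def __post_init__(self):
        if not (self.w_gc >= 0.0 and self.w_hp >= 0.0):
            raise ValueError("weights must be finite and non-negative")


def gc_content(seq: str) -> float:
    """Fraction of G and C bases in *seq*. Empty input is a domain error."""
    validate_dna(seq)
    if not seq:
        raise EmptySequenceError("GC content of an empty sequence is undefined")
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of one repeated base (0 for empty input)."""
    validate_dna(seq)
    if not seq:
        return 0
    return max(len(m.group(0)) for m in _RUN_RE.finditer(seq))


@dataclass(frozen=True)
class ConstraintVerdict:
    """Outcome of the C1/C2 check; ``reasons`` names each violated rule."""

    passed: bool
    reasons: tuple = ()
    gc: float = 0.0
    max_run: int = 0

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "reasons": list(self.reasons),
            "gc": self.gc,
            "max_run": self.max_run,
        }


def check_c1_c2(seq: str, thresholds: ConstraintThresholds) -> ConstraintVerdict:
    """Check the GC window (C1) and the homopolymer bound (C2)."""
    gc = gc_content(seq)
    run = max_homopolymer_run(seq)
    reasons = []
    if not (thresholds.gc_low <= gc <= thresholds.gc_high):
        reasons.append("C1")
    if run > thresholds.max_homopolymer:
        reasons.append("C2")
    return ConstraintVerdict(
        passed=not reasons, reasons=tuple(reasons), gc=gc, max_run=run
    )


def excess_homopolymer_mass(seq: str, max_homopolymer: int) -> int:
    """Total number of bases by which maximal runs exceed the bound."""
    validate_dna(seq)
    excess = 0
    for m in _RUN_RE.finditer(seq):
        run = len(m.group(0))
        if run > max_homopolymer:
            excess += run - max_homopolymer
    return excess


def error_score(
    seq: str,
    weights: ErrorWeights = ErrorWeights(),
    thresholds: ConstraintThresholds = ConstraintThresholds(),
) -> float:
    """Weighted scalar defect of *seq* with respect to C1 and C2.

    Zero iff GC is exactly 50% and no homopolymer run exceeds the bound.
    """
    if not seq:
        raise EmptySequenceError("error of an empty sequence is undefined")
    gc_term = abs(gc_content(seq) - 0.5)
    hp_term = excess_homopolymer_mass(seq, thresholds.max_homopolymer) / len(seq)
    return weights.w_gc * gc_term + weights.w_hp * hp_term
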