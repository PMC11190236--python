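"""Synonymous recoding of coding sequences.

Three modes mirror the transgene designs this package analyzes:
full optimization (every codon replaced by its most common synonym),
de-optimization (least common synonym), and motif-preserving recoding
(optimize everywhere except windows — e.g. RBP binding sites — where the
endogenous codons are kept so the binding-site nucleotides survive intact).
Every mode preserves the encoded protein exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .codon_usage import (
    GENETIC_CODE,
    STOP_CODONS,
    SYNONYM_FAMILIES,
    WeightTable,
    codon_class,
    split_codons,
)
from .io_core import canonical_nt

Span = tuple[int, int]  # 0-based half-open, nucleotide coordinates


def translate(cds: str, strict: bool = False) -> str:
    """Standard-code translation; terminal stop rendered '*', N-containing
    codons as 'X'. With ``strict``, an internal stop is an error."""
    codons = split_codons(cds)
    out = []
    for i, codon in enumerate(codons):
        if "N" in codon:
            out.append("X")
            continue
        aa = GENETIC_CODE[codon]
        if aa == "*" and strict and i < len(codons) - 1:
            raise ValueError(f"internal stop codon at codon {i + 1}")
        out.append(aa)
    return "".join(out)


def _best_synonym(codon: str, weights: WeightTable, minimize: bool = False) -> str:
    """Max-w (or min-w) synonym; ties broken lexicographically."""
    if codon in STOP_CODONS:
        return codon  # stop codons pass through unmodified
    family = SYNONYM_FAMILIES[GENETIC_CODE[codon]]
    extreme = min if minimize else max
    target = extreme(weights[c] for c in family)
    # lexicographically first among the tied extreme-w synonyms
    return min(c for c in family if weights[c] == target)


def optimize_cds(cds: str, weights: WeightTable) -> str:
    """Replace each sense codon with its most common synonym.

    The result encodes the same protein and has CAI = 1.0 by construction.
    """
    return "".join(
        _best_synonym(c, weights) if "N" not in c else c for c in split_codons(cds)
    )


def deoptimize_cds(cds: str, weights: WeightTable) -> str:
    """Replace each sense codon with its least common synonym."""
    return "".join(
        _best_synonym(c, weights, minimize=True) if "N" not in c else c
        for c in split_codons(cds)
    )


def merge_spans(spans: Sequence[Span]) -> list[Span]:
    merged: list[Span] = []
    for start, end in sorted(spans):
        if start > end:
            raise ValueError(f"span ({start}, {end}) has start > end")
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def preserved_codon_indices(spans: Sequence[Span], n_codons: int) -> set[int]:
    """Codon indices touched by any nucleotide window (windows expand
    outward to codon boundaries: a codon is preserved if any of its 3 nt
    overlaps a window)."""
    preserved: set[int] = set()
    for start, end in merge_spans(spans):
        if start < 0 or end > 3 * n_codons:
            raise ValueError(f"window ({start}, {end}) outside CDS of {3 * n_codons} nt")
        if end > start:
            preserved.update(range(start // 3, (end - 1) // 3 + 1))
    return preserved


def motif_preserving_recode(
    endogenous_cds: str, weights: WeightTable, preserved_windows: Sequence[Span]
) -> str:
    """Optimize every codon except those overlapping a preserved window
    (nucleotide coordinates), which keep the endogenous codon."""
    codons = split_codons(endogenous_cds)
    keep = preserved_codon_indices(preserved_windows, len(codons))
    return "".join(
        c if i in keep or "N" in c else _best_synonym(c, weights)
        for i, c in enumerate(codons)
    )


@dataclass(frozen=True)
class CompositionProfile:
    """Codon-class composition of a CDS split at a breakpoint."""

    breakpoint: int  # codon index; 5' segment = [0, breakpoint)
    fraction_common_5p: float
    fraction_rare_3p: float
    classes: tuple[str, ...]

    @property
    def n_codons(self) -> int:
        return len(self.classes)


def composition_profile(
    cds: str, weights: WeightTable, breakpoint: int
) -> CompositionProfile:
    """Per-segment codon-class fractions around a design breakpoint, e.g. a
    reporter built as a 5' common-codon block followed by a 3' rare block."""
    codons = split_codons(cds)
    sense = [c for c in codons if c not in STOP_CODONS and "N" not in c]
    if not 0 < breakpoint < len(sense):
        raise ValueError(f"breakpoint {breakpoint} out of range (0, {len(sense)})")
    classes = tuple(codon_class(c, weights) for c in sense)
    head, tail = classes[:breakpoint], classes[breakpoint:]
    return CompositionProfile(
        breakpoint,
        head.count("common") / len(head),
        tail.count("rare") / len(tail),
        classes,
    )


def attach_tags(cds: str, tag5: str = "", tag3: str = "") -> str:
    """Concatenate in-frame 5' and 3' tag sequences (e.g. an epitope tag
    and a nanobody antigen tag) onto a CDS; frame is preserved."""
    tag5, tag3, cds = canonical_nt(tag5), canonical_nt(tag3), canonical_nt(cds)
    for label, tag in (("5'", tag5), ("3'", tag3)):
        if len(tag) % 3 != 0:
            raise ValueError(f"{label} tag length {len(tag)} not divisible by 3")
    return tag5 + cds + tag3
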