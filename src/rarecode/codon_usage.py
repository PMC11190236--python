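"""Codon-usage tables, relative adaptiveness, and CAI.

The codon adaptation index (CAI) of a coding sequence is the geometric mean
of the relative adaptiveness w of its codons, where for each codon
``w = f / max(f over synonymous codons)`` and f comes from a genome-wide
usage table. CAI = 1 means every position uses the most common synonym.

Conventions (CAIcal-compatible): the terminal stop codon is excluded from
scoring; Met and Trp are scored (their single-codon families have w = 1);
codons containing N are skipped and tallied. A coding genome's CAI values
here are binned as rare (< 0.68), mid ([0.68, 0.78]) and common (> 0.78).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import exp, log
from typing import Iterable, Literal, Mapping

from Bio.Data import CodonTable

from .io_core import FormatError, canonical_nt

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: codon -> single-letter amino acid (standard code, DNA alphabet), '*' = stop
GENETIC_CODE: dict[str, str] = dict(CodonTable.standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    GENETIC_CODE[_stop] = "*"

#: amino acid -> sorted tuple of synonymous codons (sense codons only)
SYNONYM_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(GENETIC_CODE.items()):
    if _aa != "*":
        SYNONYM_FAMILIES.setdefault(_aa, ())
        SYNONYM_FAMILIES[_aa] += (_codon,)

ALL_CODONS = tuple(sorted(GENETIC_CODE))

CAIBinLabel = Literal["rare", "mid", "common"]
DEFAULT_BIN_BOUNDARIES: tuple[float, float] = (0.68, 0.78)


@dataclass(frozen=True)
class CodonUsageTable:
    """Genome-wide codon frequencies plus the standard genetic code."""

    frequencies: Mapping[str, float]  # codon -> per-thousand or raw count
    unit: str = "per_thousand"
    organism: str = ""

    def __post_init__(self) -> None:
        codons = set(self.frequencies)
        if codons != set(ALL_CODONS):
            missing = sorted(set(ALL_CODONS) - codons)
            extra = sorted(codons - set(ALL_CODONS))
            raise FormatError(
                f"usage table must contain exactly the 64 codons; "
                f"missing={missing[:5]} extra={extra[:5]}"
            )
        if any(f < 0 for f in self.frequencies.values()):
            raise FormatError("usage table frequencies must be >= 0")

    def family(self, amino_acid: str) -> tuple[str, ...]:
        return SYNONYM_FAMILIES[amino_acid]


@dataclass(frozen=True)
class WeightTable:
    """Relative adaptiveness w per sense codon; max within each family is 1."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        for codon, w in self.weights.items():
            if codon in STOP_CODONS:
                raise ValueError(f"stop codon {codon} has no relative adaptiveness")
            if not 0 < w <= 1:
                raise ValueError(f"w({codon}) = {w} outside (0, 1]")

    def __getitem__(self, codon: str) -> float:
        return self.weights[codon]

    def family_weights(self, amino_acid: str) -> dict[str, float]:
        return {c: self.weights[c] for c in SYNONYM_FAMILIES[amino_acid]}


@dataclass(frozen=True)
class CAIScore:
    gene_id: str
    cai: float
    n_codons_scored: int
    n_codons_skipped: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cai <= 1:
            raise ValueError(f"{self.gene_id}: CAI {self.cai} outside (0, 1]")
        if self.n_codons_scored < 1:
            raise ValueError(f"{self.gene_id}: no codons scored")


_KAZUSA_ENTRY = re.compile(r"([ACGTUacgtu]{3})\s+([\d.]+)\s*\(\s*([\d]+)\s*\)")


def parse_usage_table(text: str, organism: str = "") -> CodonUsageTable:
    """Parse Kazusa-style ``codon frequency ( count )`` text into a table.

    Frequencies are taken as printed (per thousand); the raw counts in
    parentheses are ignored beyond validation. Requires all 64 codons,
    each exactly once.
    """
    freqs: dict[str, float] = {}
    for codon_raw, freq, _count in _KAZUSA_ENTRY.findall(text):
        codon = canonical_nt(codon_raw)
        if codon in freqs:
            raise FormatError(f"duplicate codon {codon} in usage table")
        freqs[codon] = float(freq)
    if len(freqs) != 64:
        missing = sorted(set(ALL_CODONS) - set(freqs))
        raise FormatError(f"usage table has {len(freqs)} codons, expected 64; missing {missing[:6]}")
    return CodonUsageTable(freqs, unit="per_thousand", organism=organism)


def relative_adaptiveness(table: CodonUsageTable, zero_floor: float = 1e-3) -> WeightTable:
    """w = f / max(f over synonyms) per sense codon.

    A zero-frequency codon in a family with a nonzero maximum receives the
    configurable floor ``zero_floor`` so downstream geometric means stay
    finite. A family whose frequencies are all zero is an error.
    """
    weights: dict[str, float] = {}
    for _aa, family in SYNONYM_FAMILIES.items():
        fmax = max(table.frequencies[c] for c in family)
        if fmax == 0:
            raise ValueError(f"all-zero synonymous family {family}")
        for c in family:
            w = table.frequencies[c] / fmax
            weights[c] = w if w > 0 else zero_floor
    return WeightTable(weights)


def split_codons(cds: str) -> list[str]:
    cds = canonical_nt(cds)
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def compute_cai(cds: str, weights: WeightTable, gene_id: str = "") -> CAIScore:
    """Geometric mean of w over all scored sense codons of a CDS.

    The terminal stop codon (if present) is excluded; codons containing N
    are skipped and counted; an internal stop codon is an error.
    """
    codons = split_codons(cds)
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    log_sum = 0.0
    scored = 0
    skipped = 0
    for i, codon in enumerate(codons):
        if "N" in codon:
            skipped += 1
            continue
        if codon in STOP_CODONS:
            raise ValueError(f"{gene_id or 'CDS'}: internal stop codon {codon} at codon {i + 1}")
        log_sum += log(weights[codon])
        scored += 1
    if scored == 0:
        raise ValueError(f"{gene_id or 'CDS'}: zero scorable codons")
    return CAIScore(gene_id or "CDS", exp(log_sum / scored), scored, skipped)


def cai_bin(
    cai: float | CAIScore, boundaries: tuple[float, float] = DEFAULT_BIN_BOUNDARIES
) -> CAIBinLabel:
    """Bin a CAI: rare = [0, lo); mid = [lo, hi]; common = (hi, 1]."""
    lo, hi = boundaries
    if not lo < hi:
        raise ValueError("bin boundaries must be strictly increasing")
    value = cai.cai if isinstance(cai, CAIScore) else cai
    if value < lo:
        return "rare"
    if value <= hi:
        return "mid"
    return "common"


def codon_class(
    codon: str, weights: WeightTable, rare_threshold: float | None = None
) -> Literal["common", "rare", "intermediate"]:
    """Classify a sense codon within its synonymous family.

    Default rule: common iff w = 1 (family maximum; single-codon families
    are common), rare iff w equals the family minimum in a multi-codon
    family, else intermediate. Passing ``rare_threshold`` switches to a
    frequency-threshold mode: rare iff w < threshold, common otherwise.
    """
    codon = canonical_nt(codon)
    aa = GENETIC_CODE.get(codon)
    if aa is None or aa == "*":
        raise ValueError(f"{codon} is not a sense codon")
    w = weights[codon]
    if rare_threshold is not None:
        return "rare" if w < rare_threshold else "common"
    fam = weights.family_weights(aa)
    if w == max(fam.values()):
        return "common"
    if w == min(fam.values()):
        return "rare"
    return "intermediate"


def genome_cai_percentile(score: CAIScore | float, genome_scores: Iterable[CAIScore | float]) -> float:
    """Percentile of a CAI within a genome-wide set: 100 × fraction of
    genome scores strictly below the query. A query below every genome
    score returns 0; above all of n scores returns 100·(n−1)/n when the
    maximum is in the set (strict comparison)."""
    values = [s.cai if isinstance(s, CAIScore) else float(s) for s in genome_scores]
    if not values:
        raise ValueError("empty genome score set")
    q = score.cai if isinstance(score, CAIScore) else float(score)
    below = sum(1 for v in values if v < q)
    return 100.0 * below / len(values)
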