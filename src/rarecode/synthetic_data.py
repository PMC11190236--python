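"""Seeded generators for every input format the pipeline consumes.

Each generator is a pure function of (parameters, seed) — identical calls
give byte-identical outputs — and returns a SyntheticTruth carrying the
planted structure (target CAI, motif positions, enriched gene ids, decay
constants, regulated genes) so tests can assert exact recovery.

Default parameters emulate the study conditions: a usage-table synonym
skew of 4 (a typical genome-wide max:min synonym ratio), reporter-panel
CAIs spanning ~0.58–1.0, 1000-gene expression matrices with planted
cell-type-specific genes, first-order mRNA decay over a 1-hour
transcription shutoff, and a differential-expression table whose regulated
subset is biased toward low-CAI genes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from math import exp, log
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_usage import (
    ALL_CODONS,
    STOP_CODONS,
    SYNONYM_FAMILIES,
    CodonUsageTable,
    WeightTable,
    compute_cai,
)
from .motif_scan import NT_ORDER, PWM, ScoreDistribution, scan

AMINO_ACIDS = "".join(sorted(SYNONYM_FAMILIES))


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted parameters of one generated dataset; sufficient to
    recompute every expected downstream output."""

    seed: int
    generator: str
    planted: dict

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")


def synth_usage_table(seed: int, skew: float = 4.0) -> CodonUsageTable:
    """A valid 64-codon table where every multi-codon family spans a
    max:min frequency ratio of ``skew``. skew = 1 degenerates to equal
    synonym frequencies (every codon classifies as common)."""
    if skew < 1:
        raise ValueError("skew must be >= 1")
    rng = np.random.default_rng(seed)
    freqs: dict[str, float] = {c: 1.0 for c in STOP_CODONS}
    for _aa, family in sorted(SYNONYM_FAMILIES.items()):
        values = np.linspace(1.0, skew, len(family))
        order = rng.permutation(len(family))
        for codon, value in zip(family, values[order]):
            freqs[codon] = float(value)
    return CodonUsageTable(freqs, unit="per_thousand", organism=f"synthetic(seed={seed})")


def format_kazusa(table: CodonUsageTable) -> str:
    """Render a usage table in Kazusa ``codon freq ( count )`` layout."""
    entries = []
    for codon in ALL_CODONS:
        f = table.frequencies[codon]
        entries.append(f"{codon.replace('T', 'U')} {f:6.1f}({int(round(f * 100)):7d})")
    lines = ["  ".join(entries[i : i + 4]) for i in range(0, 64, 4)]
    return "\n".join(lines) + "\n"


def min_attainable_cai(weights: WeightTable) -> float:
    """Geometric mean of family-minimum w over the 20 amino acids — the
    lowest CAI reachable by any synonymous recoding of an average protein."""
    logs = [
        log(min(weights[c] for c in fam)) for fam in SYNONYM_FAMILIES.values()
    ]
    return exp(sum(logs) / len(logs))


def synth_cds(
    n_codons: int,
    target_cai: float,
    weights: WeightTable,
    seed: int,
    tol: float = 0.005,
) -> tuple[str, SyntheticTruth]:
    """A CDS with CAI within ``tol`` of ``target_cai``.

    A fixed random protein is drawn for the seed; positions are then
    assigned either the max-w or min-w synonym, with the count of min-w
    positions chosen by monotone search on the log-CAI and refined by
    single-position swaps. Raises if the target lies outside the
    attainable range for the drawn protein.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    protein = "".join(rng.choice(list(AMINO_ACIDS), size=n_codons))
    max_codons, min_codons, log_min = [], [], []
    for aa in protein:
        fam = {c: weights[c] for c in SYNONYM_FAMILIES[aa]}
        cmax = min(c for c, w in fam.items() if w == max(fam.values()))
        cmin = min(c for c, w in fam.items() if w == min(fam.values()))
        max_codons.append(cmax)
        min_codons.append(cmin)
        log_min.append(log(weights[cmin]))
    lo = exp(sum(log_min) / n_codons)
    if not lo - tol <= target_cai <= 1.0 + tol:
        raise ValueError(
            f"target CAI {target_cai} outside attainable range [{lo:.4f}, 1.0] "
            f"for this protein"
        )
    order = rng.permutation(n_codons)
    prefix = np.concatenate([[0.0], np.cumsum(np.asarray(log_min)[order])])
    achieved = np.exp(prefix / n_codons)
    k = int(np.argmin(np.abs(achieved - target_cai)))
    chosen = set(order[:k].tolist())
    # single-swap refinement: exchange a selected/unselected pair whose
    # log-w difference moves the geometric mean closer to the target
    current = float(prefix[k])
    target_log_sum = n_codons * log(target_cai) if target_cai > 0 else current
    for _ in range(2 * n_codons):
        err = current - target_log_sum
        if abs(exp(current / n_codons) - target_cai) <= tol:
            break
        best = None
        for i in range(n_codons):
            delta = -log_min[i] if i in chosen else log_min[i]
            if abs(err + delta) < abs(err) - 1e-12:
                best = (i, delta)
                break
        if best is None:
            break
        i, delta = best
        chosen.symmetric_difference_update({i})
        current += delta
    cds = "".join(
        min_codons[i] if i in chosen else max_codons[i] for i in range(n_codons)
    )
    score = compute_cai(cds, weights)
    if abs(score.cai - target_cai) > tol:
        raise ValueError(
            f"could not reach CAI {target_cai} within {tol}; achieved {score.cai:.4f}"
        )
    truth = SyntheticTruth(
        seed,
        "synth_cds",
        {"n_codons": n_codons, "target_cai": target_cai, "achieved_cai": score.cai,
         "protein": protein},
    )
    return cds, truth


def synth_background(length: int, seed: int, composition: Sequence[float] = (0.25,) * 4) -> str:
    """Random nucleotide string from a stated base composition."""
    rng = np.random.default_rng(seed)
    comp = np.asarray(composition, float)
    comp = comp / comp.sum()
    return "".join(rng.choice(list(NT_ORDER), size=length, p=comp))


def plant_motifs(
    utr3: str,
    motif_consensus: str,
    positions: Sequence[int],
    seed: int,
    pwm: PWM | None = None,
    dist: ScoreDistribution | None = None,
    alpha: float = 0.005,
    max_rounds: int = 100,
) -> tuple[str, SyntheticTruth]:
    """Write the exact consensus at each position of a background string.

    Positions must be non-overlapping and in bounds. When a PWM is given,
    background stretches that spuriously reach significance are resampled
    (rejection sampling) from the PWM's background composition, so the only
    significant hits are the planted ones.
    """
    word = motif_consensus.upper().replace("U", "T")
    L = len(word)
    spans = sorted((p, p + L) for p in positions)
    for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping motif positions at {s1} and {s2}")
    if spans and (spans[0][0] < 0 or spans[-1][1] > len(utr3)):
        raise ValueError("motif position out of bounds")
    seq = list(utr3.upper().replace("U", "T"))
    for start, end in spans:
        seq[start:end] = word
    planted = set(positions)
    if pwm is not None:
        rng = np.random.default_rng(seed)
        comp = pwm.background / pwm.background.sum()
        for _ in range(max_rounds):
            hits = scan("".join(seq), pwm, dist, alphas=(alpha, alpha))
            spurious = [
                h for h in hits.hits
                if not any(s - L < h.start < e for s, e in spans)
            ]
            if not spurious:
                break
            for h in spurious:
                for i in range(h.start, h.start + pwm.length):
                    if not any(s <= i < e for s, e in spans):
                        seq[i] = rng.choice(list(NT_ORDER), p=comp)
        else:
            raise RuntimeError("rejection sampling failed to remove spurious hits")
    truth = SyntheticTruth(
        seed, "plant_motifs",
        {"consensus": word, "positions": sorted(planted), "length": len(seq)},
    )
    return "".join(seq), truth


def synth_expression(
    n_genes: int = 1000,
    cell_types: Sequence[str] = ("neuroblast", "neuron", "glia"),
    n_enriched_per_type: int = 50,
    effect_size: float = 100.0,
    dispersion: float = 1.0,
    within_sd: float = 0.1,
    seed: int = 0,
    dataset: str = "synthetic",
):
    """FPKM matrix with planted cell-type-specific genes.

    Background abundance is log-normal (the pipeline consumes normalized
    values, not counts): each gene draws a shared baseline (log-sd
    ``dispersion``) that is common to all cell types — emulating the strong
    cross-cell-type correlation of real expression data — plus independent
    per-cell-type log-noise (``within_sd``). Each planted gene is then
    multiplied by ``effect_size`` in its home cell type and divided by it
    elsewhere; effect_size = 1 plants no structure, and dispersion = 0
    makes the columns fully independent.
    """
    from .enrichment import ExpressionMatrix

    if effect_size < 1:
        raise ValueError("effect_size must be >= 1")
    if n_enriched_per_type * len(cell_types) > n_genes:
        raise ValueError("more planted genes than genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    baseline = rng.normal(log(10.0), dispersion, size=n_genes)
    planted: dict[str, list[str]] = {}
    cursor = 0
    shuffled = rng.permutation(n_genes)
    # planted markers draw from the central baseline range (within 2 sd):
    # cell-type marker genes are not extreme-abundance outliers
    n_planted_total = n_enriched_per_type * len(cell_types)
    if n_planted_total and dispersion > 0:
        idx = shuffled[:n_planted_total]
        baseline[idx] = np.clip(
            baseline[idx], log(10.0) - 2 * dispersion, log(10.0) + 2 * dispersion
        )
    values = np.exp(
        baseline[:, None] + rng.normal(0.0, within_sd, size=(n_genes, len(cell_types)))
    )
    for j, ct in enumerate(cell_types):
        idx = shuffled[cursor : cursor + n_enriched_per_type]
        cursor += n_enriched_per_type
        planted[ct] = sorted(genes[i] for i in idx)
        if effect_size > 1:
            values[idx, j] *= effect_size
            others = [c for c in range(len(cell_types)) if c != j]
            values[np.ix_(idx, others)] /= effect_size
    df = pd.DataFrame(values, index=genes, columns=list(cell_types))
    matrix = ExpressionMatrix(df, unit="FPKM", dataset=dataset)
    truth = SyntheticTruth(
        seed, "synth_expression",
        {"planted": planted, "effect_size": effect_size, "n_genes": n_genes},
    )
    return matrix, truth


def synth_ct_table(
    decay_constants: Mapping[str, float],
    genotype_effects: Mapping[str, float],
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    t_hours: float = 1.0,
    seed: int = 0,
    reference_ct: float = 17.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """qRT-PCR CT table for a transcription-shutoff decay experiment.

    ``decay_constants`` maps gene -> first-order k (per hour) in the
    reference genotype; ``genotype_effects`` maps genotype -> multiplier on
    k. Treated target CTs rise by k·t/ln2 cycles (2^ΔCT arithmetic of
    exp(−kt) decay) plus Gaussian CT noise; the housekeeping reference is
    constant.
    """
    if any(k < 0 for k in decay_constants.values()):
        raise ValueError("decay constants must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for gene, k in sorted(decay_constants.items()):
        baseline = float(rng.uniform(20, 26))
        for genotype, mult in sorted(genotype_effects.items()):
            k_eff = k * mult
            for rep in range(n_replicates):
                for treatment, shift in (
                    ("none", 0.0),
                    ("ActD", k_eff * t_hours / log(2.0)),
                ):
                    ct = baseline + shift + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
                    rows.append(
                        {
                            "sample": f"{gene}_{genotype}_{treatment}_r{rep + 1}",
                            "gene": gene,
                            "genotype": genotype,
                            "treatment": treatment,
                            "replicate": rep + 1,
                            "timepoint_min": 60.0 * t_hours if treatment == "ActD" else 0.0,
                            "target_ct": ct,
                            "ref_ct": reference_ct,
                        }
                    )
    truth = SyntheticTruth(
        seed, "synth_ct_table",
        {
            "decay_constants": dict(decay_constants),
            "genotype_effects": dict(genotype_effects),
            "t_hours": t_hours,
            "noise_sd": noise_sd,
            "expected_remaining": {
                f"{g}:{gt}": exp(-k * m * t_hours)
                for g, k in decay_constants.items()
                for gt, m in genotype_effects.items()
            },
        },
    )
    return pd.DataFrame(rows), truth


def synth_de_table(
    cai_map: Mapping[str, float],
    n_regulated: int,
    rare_bias: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """DE table (gene, log2FC, padj, direction) with a regulated subset
    sampled with probability weighted toward low-CAI genes.

    rare_bias = 0 draws the regulated set uniformly; rare_bias = 1 draws
    it entirely from the lowest-CAI decile. Regulated genes are
    "up_by_orb2": decreased on depletion of the regulator, so log2FC < 0
    and padj small.
    """
    if not 0 <= rare_bias <= 1:
        raise ValueError("rare_bias must be in [0, 1]")
    genes = sorted(cai_map)
    n_genes = len(genes)
    if n_regulated > n_genes:
        raise ValueError("n_regulated exceeds number of genes")
    rng = np.random.default_rng(seed)
    cais = np.array([cai_map[g] for g in genes])
    decile_cut = np.quantile(cais, 0.10)
    in_decile = (cais <= decile_cut).astype(float)
    if in_decile.sum() < n_regulated and rare_bias == 1.0:
        raise ValueError("lowest-CAI decile smaller than n_regulated")
    weights = (1 - rare_bias) * np.ones(n_genes) / n_genes
    if in_decile.sum() > 0:
        weights = weights + rare_bias * in_decile / in_decile.sum()
    weights = weights / weights.sum()
    regulated = set(rng.choice(genes, size=n_regulated, replace=False, p=weights))
    rows = []
    for g in genes:
        if g in regulated:
            rows.append(
                {
                    "gene": g,
                    "log2FC": -abs(rng.normal(1.5, 0.5)),
                    "padj": float(10 ** -rng.uniform(2, 8)),
                    "direction": "up_by_orb2",
                }
            )
        else:
            rows.append(
                {
                    "gene": g,
                    "log2FC": float(rng.normal(0, 0.2)),
                    "padj": float(rng.uniform(0.05, 1.0)),
                    "direction": "unchanged",
                }
            )
    truth = SyntheticTruth(
        seed, "synth_de_table",
        {"regulated": sorted(regulated), "rare_bias": rare_bias},
    )
    return pd.DataFrame(rows), truth
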