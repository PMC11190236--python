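"""Numeric reductions of molecular measurements.

Covers 2^ΔCT relative mRNA abundance from qRT-PCR (ΔCT = CT_reference −
CT_target, so larger values mean more target), transcription-shutoff
(actinomycin D) decay ratios with a genotype comparison by Welch's t-test,
normalization of per-sample measurements to slide controls, and the
protein-per-mRNA output ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log
from typing import Literal, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CtMeasurement:
    sample_id: str
    genotype: str
    treatment: Literal["none", "ActD"]
    timepoint_min: float
    target_ct: float
    reference_ct: float  # housekeeping gene (RP49)

    def __post_init__(self) -> None:
        for label, ct in (("target", self.target_ct), ("reference", self.reference_ct)):
            if not np.isfinite(ct):
                raise ValueError(f"{self.sample_id}: non-finite {label} CT")


def relative_level(measurement: CtMeasurement) -> float:
    """2^(CT_reference − CT_target): relative abundance normalized to the
    housekeeping gene. Strictly increasing in CT_ref, decreasing in CT_target."""
    return 2.0 ** (measurement.reference_ct - measurement.target_ct)


@dataclass(frozen=True)
class DecayResult:
    gene: str
    genotype: str
    fractions: tuple[float, ...]  # remaining fraction per replicate

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions):
            raise ValueError("remaining fraction must be >= 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.fractions))

    @property
    def sem(self) -> float:
        arr = np.asarray(self.fractions)
        return float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")


def decay_ratio(
    treated: Sequence[float], untreated: Sequence[float], gene: str = "", genotype: str = ""
) -> DecayResult:
    """Per-replicate remaining fraction = treated / untreated relative level.

    Replicates must be paired (equal lengths).
    """
    if len(treated) != len(untreated):
        raise ValueError(
            f"unpaired replicates: {len(treated)} treated vs {len(untreated)} untreated"
        )
    if len(treated) == 0:
        raise ValueError("no replicates")
    if any(u <= 0 for u in untreated):
        raise ValueError("untreated level must be > 0")
    fractions = tuple(t / u for t, u in zip(treated, untreated))
    return DecayResult(gene, genotype, fractions)


def compare_decay(
    group_a: Sequence[float],
    group_b: Sequence[float],
    pooled: bool = False,
) -> tuple[float, float]:
    """Two-sample two-tailed t-test on remaining fractions (Welch by
    default; ``pooled`` switches to equal-variance). Returns (t, p); the
    sign of t reports direction (A − B)."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 replicates")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.pvalue)


def normalize_to_control(values: Sequence[float], control_values: Sequence[float]) -> np.ndarray:
    """Divide each measurement by the mean of the same-slide controls."""
    controls = np.asarray(control_values, float)
    if controls.size == 0:
        raise ValueError("no control values")
    mean = controls.mean()
    if mean <= 0:
        raise ValueError("control mean must be > 0")
    return np.asarray(values, float) / mean


def protein_per_mrna(mean_protein_norm: float, mean_mrna_norm: float) -> float:
    """100 × (normalized protein abundance) / (normalized mRNA abundance).

    Protein output per mRNA, as a percentage of the normalization control.
    """
    if mean_mrna_norm <= 0:
        raise ValueError("mRNA mean must be > 0")
    return 100.0 * mean_protein_norm / mean_mrna_norm


def fit_half_life(timepoints_min: Sequence[float], fractions: Sequence[float]) -> float:
    """Optional extra beyond the single-timepoint ratios: first-order decay
    half-life (minutes) from log-linear least squares through the origin."""
    t = np.asarray(timepoints_min, float)
    f = np.asarray(fractions, float)
    if (f <= 0).any():
        raise ValueError("fractions must be > 0 for log-linear fitting")
    if np.allclose(t, 0):
        raise ValueError("need nonzero timepoints")
    k = -float(np.sum(t * np.log(f)) / np.sum(t * t))  # ln f = -k t
    if k <= 0:
        return float("inf")
    return log(2.0) / k
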