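"""CAI × binding-site convergence statistics.

Three analyses: an ordinary least-squares regression of binding-site count
on CAI across a reporter panel; per-CAI-bin regressions of binding-site
density on CAI for differentially regulated gene sets (the rare bin is
where an inverse correlation — more sites at lower CAI — is expected for
genes positively regulated by the RBP); and a candidate filter cascade that
narrows regulated genes by CAI, binding-site density, independent binding
evidence, and known brain function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_usage import DEFAULT_BIN_BOUNDARIES, CAIBinLabel, cai_bin

Direction = Literal["up_by_orb2", "down_by_orb2", "unchanged"]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    cai: float
    site_count: int
    region_length: int  # nt of scanned region (3' CDS quartile + 3'UTR)
    direction: Direction = "unchanged"
    log2fc: float = float("nan")
    padj: float = float("nan")

    def __post_init__(self) -> None:
        if self.site_count < 0:
            raise ValueError(f"{self.gene_id}: negative site count")
        if self.region_length <= 0:
            raise ValueError(f"{self.gene_id}: non-positive region length")

    @property
    def site_density(self) -> float:
        """Sites per kilobase of scanned region."""
        return self.site_count / (self.region_length / 1000.0)


@dataclass(frozen=True)
class RegressionResult:
    n: int
    slope: float
    intercept: float
    r: float
    pvalue: float
    label: str = ""
    sufficient: bool = True  # False when n < 3 (no meaningful p-value)

    def __post_init__(self) -> None:
        if self.sufficient and not abs(self.r) <= 1 + 1e-12:
            raise ValueError(f"|r| = {abs(self.r)} > 1")


def ols_fit(x: Sequence[float], y: Sequence[float], label: str = "") -> RegressionResult:
    """Least-squares line with Pearson r and its two-sided p (t, n−2 df)."""
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    if xa.size < 2:
        raise ValueError("need at least 2 points")
    if np.allclose(xa, xa[0]):
        raise ValueError("zero variance in x")
    if np.allclose(ya, ya[0]):
        # constant response: flat line, no correlation
        return RegressionResult(int(xa.size), 0.0, float(ya[0]), 0.0, 1.0,
                                label=label, sufficient=xa.size >= 3)
    fit = stats.linregress(xa, ya)
    return RegressionResult(
        n=int(xa.size),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        pvalue=float(fit.pvalue),
        label=label,
        sufficient=xa.size >= 3,
    )


def reporter_regression(reporters: Sequence[tuple[float, float]], label: str = "reporters") -> RegressionResult:
    """Regression of binding-site count on CAI across a reporter panel
    (an inverse relationship is the expected signature)."""
    if len(reporters) < 3:
        raise ValueError("need at least 3 reporters")
    cais = [c for c, _ in reporters]
    sites = [s for _, s in reporters]
    return ols_fit(cais, sites, label=label)


def binned_regression(
    records: Sequence[GeneRecord],
    boundaries: tuple[float, float] = DEFAULT_BIN_BOUNDARIES,
    direction: Direction | None = None,
) -> dict[CAIBinLabel, RegressionResult]:
    """Per-CAI-bin OLS of site density on CAI.

    Bins with fewer than 3 records are flagged (``sufficient=False``) with
    NaN statistics rather than dropped silently.
    """
    if not records:
        raise ValueError("no gene records")
    if direction is not None:
        records = [r for r in records if r.direction == direction]
    out: dict[CAIBinLabel, RegressionResult] = {}
    for label in ("rare", "mid", "common"):
        group = [r for r in records if cai_bin(r.cai, boundaries) == label]
        if len(group) >= 3 and not np.allclose(
            [g.cai for g in group], group[0].cai
        ):
            out[label] = ols_fit(
                [g.cai for g in group], [g.site_density for g in group], label=label
            )
        else:
            out[label] = RegressionResult(
                n=len(group), slope=float("nan"), intercept=float("nan"),
                r=float("nan"), pvalue=float("nan"), label=label, sufficient=False,
            )
    return out


@dataclass(frozen=True)
class CascadeStage:
    name: str
    parameter: str
    genes: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class CascadeReport:
    stages: tuple[CascadeStage, ...]
    input_size: int
    skipped_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for prev, cur in zip(self.stages, self.stages[1:]):
            if not cur.genes <= prev.genes:
                raise ValueError(f"stage {cur.name!r} is not a subset of {prev.name!r}")

    @property
    def counts(self) -> list[int]:
        return [s.count for s in self.stages]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [s.name for s in self.stages],
                "parameter": [s.parameter for s in self.stages],
                "surviving": self.counts,
                "genes": [",".join(sorted(s.genes)) for s in self.stages],
            }
        )


def candidate_cascade(
    de_table: pd.DataFrame,
    cai_map: Mapping[str, float],
    density_map: Mapping[str, float],
    binding_evidence: Iterable[str],
    brain_genes: Iterable[str],
    cai_max: float = 0.68,
    min_density: float = 9.0,
    direction: Direction = "up_by_orb2",
) -> CascadeReport:
    """Stepwise candidate filter, in the fixed published order:

    0. genes with the requested DE direction (default: up-regulated by the
       RBP, i.e. decreased on its depletion);
    1. CAI strictly below ``cai_max``;
    2. binding-site density strictly above ``min_density`` sites/kb over
       the scanned region;
    3. membership in an independent binding-evidence gene set;
    4. membership in a known-brain-function gene set.

    Genes missing from the CAI or density maps are collected into
    ``skipped_genes`` (reported, never silently dropped).
    """
    required = {"gene", "direction"}
    if not required <= set(de_table.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    selected = set(de_table.loc[de_table["direction"] == direction, "gene"])
    skipped = frozenset(g for g in selected if g not in cai_map or g not in density_map)
    stage0 = frozenset(selected - skipped)
    stage1 = frozenset(g for g in stage0 if cai_map[g] < cai_max)
    stage2 = frozenset(g for g in stage1 if density_map[g] > min_density)
    stage3 = stage2 & frozenset(binding_evidence)
    stage4 = stage3 & frozenset(brain_genes)
    stages = (
        CascadeStage("de_direction", direction, stage0),
        CascadeStage("cai_below", f"CAI < {cai_max}", stage1),
        CascadeStage("density_above", f"> {min_density} sites/kb", stage2),
        CascadeStage("binding_evidence", "published binding datasets", stage3),
        CascadeStage("brain_role", "known role in the brain", stage4),
    )
    return CascadeReport(stages, input_size=len(de_table), skipped_genes=skipped)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (emitted alongside raw
    regression p for transparency)."""
    p = np.asarray(pvalues, float)
    return stats.false_discovery_control(p, method="bh")
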