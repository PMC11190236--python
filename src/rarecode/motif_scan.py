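"""PWM motif scanning with exact p-values over the 3' end of transcripts.

The scan region is the last quartile of the CDS (codon-boundary aligned,
ceiling rule) concatenated with the 3'UTR — the portion of an mRNA where a
3'-biased RNA-binding protein such as a CPEB-family protein is expected to
act. Windows are scored as log-odds against a background model; p-values
are exact: the null distribution of the discretized score of a random
background word is built by positionwise convolution (dynamic programming,
O(L · grid · 4)), never by 4^L enumeration. Two thresholds follow the
published convention: p < 0.005 for significant hits, p < 0.01 for
suboptimal hits. Scanning is single-stranded (sense only): targets are
mRNAs. Hit counts are normalized to sites per kilobase of scanned region.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .codon_usage import WeightTable, codon_class, GENETIC_CODE
from .io_core import FormatError, TranscriptModel, canonical_nt, get_logger

NT_ORDER = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT_ORDER)}

HitClass = Literal["significant", "suboptimal"]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix (L×4, columns A,C,G,T) plus background."""

    name: str
    matrix: np.ndarray  # shape (L, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise FormatError(f"PWM matrix must be L×4 with L >= 1, got {m.shape}")
        if (m < 0).any():
            raise FormatError("PWM probabilities must be >= 0")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise FormatError("each PWM position must sum to 1 (within 1e-6)")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
            raise FormatError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """log2(p / background) per position and nucleotide.

        A zero background nucleotide with nonzero motif probability would
        give an infinite score and is rejected.
        """
        with np.errstate(divide="ignore"):
            if ((self.background == 0) & (self.matrix > 0).any(axis=0)).any():
                raise ValueError("zero-background nucleotide with nonzero motif probability")
            lo = np.log2(np.where(self.matrix > 0, self.matrix, np.nan) / self.background)
        # zero motif probability -> strongly negative finite score so a
        # mismatch is penalized but arithmetic stays finite
        return np.where(np.isnan(lo), -100.0, lo)

    @property
    def consensus(self) -> str:
        return "".join(NT_ORDER[i] for i in self.matrix.argmax(axis=1))


def load_pwm(
    path: str | Path,
    pseudocount: float = 0.0,
    background: Sequence[float] | None = None,
    name: str | None = None,
) -> PWM:
    """Load a 4×L or L×4 matrix text file (counts or probabilities).

    Lines starting with ``>`` or ``#`` are skipped; rows may carry a
    leading A/C/G/U/T label (RBPmap/MEME style). Orientation is
    auto-detected from row labels or from which axis normalizes to 1;
    counts are converted to probabilities after adding ``pseudocount``.
    """
    rows: list[list[float]] = []
    labels: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith((">", "#")):
            continue
        tokens = line.replace(":", " ").replace("|", " ").split()
        label = ""
        if tokens and tokens[0].upper() in ("A", "C", "G", "T", "U"):
            label = canonical_nt(tokens[0])
            tokens = tokens[1:]
        try:
            rows.append([float(t) for t in tokens])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell in line {raw!r}") from exc
        labels.append(label)
    if not rows:
        raise FormatError(f"{path}: empty PWM file")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged matrix rows {sorted(lengths)}")
    m = np.array(rows, dtype=float)
    m = _orient(m, labels, path)
    if pseudocount > 0 or (m.sum(axis=1) > 1.5).any():
        m = m + pseudocount
    sums = m.sum(axis=1)
    if (sums <= 0).any():
        raise FormatError(f"{path}: a PWM position has zero total mass")
    m = m / sums[:, None]
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(name or Path(path).stem, m, bg)


def _orient(m: np.ndarray, labels: list[str], path: str | Path) -> np.ndarray:
    """Return the matrix as (L, 4) with columns in ACGT order."""
    if any(labels):
        if sorted(labels) != ["A", "C", "G", "T"]:
            raise FormatError(f"{path}: row labels must be the 4 nucleotides, got {labels}")
        order = [labels.index(nt) for nt in NT_ORDER]
        return m[order].T  # labelled rows are nucleotides -> transpose
    if m.shape[0] == 4 and m.shape[1] == 4:
        rows_norm = np.allclose(m.sum(axis=1), 1.0, atol=1e-6)
        cols_norm = np.allclose(m.sum(axis=0), 1.0, atol=1e-6)
        if rows_norm == cols_norm:
            raise FormatError(f"{path}: ambiguous 4×4 matrix orientation; add row labels")
        return m if rows_norm else m.T
    if m.shape[1] == 4:
        return m
    if m.shape[0] == 4:
        return m.T
    raise FormatError(f"{path}: matrix shape {m.shape} has no axis of size 4")


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact null distribution of the discretized log-odds score.

    ``grid`` holds integer score indices (score = index × granularity);
    ``pmf`` the probability mass of each under the background model.
    """

    grid: np.ndarray  # int64, ascending
    pmf: np.ndarray
    granularity: float

    def __post_init__(self) -> None:
        if not math.isclose(float(self.pmf.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("score distribution mass must sum to 1 within 1e-9")

    @property
    def sf(self) -> np.ndarray:
        """Survival function P(K >= grid[i]); monotone non-increasing."""
        return self.pmf[::-1].cumsum()[::-1]

    def pvalue(self, score_index: int) -> float:
        """P(K >= score_index) under the background model."""
        i = int(np.searchsorted(self.grid, score_index, side="left"))
        if i >= len(self.grid):
            return 0.0
        return float(self.sf[i])

    def min_pvalue(self) -> float:
        return float(self.pmf[-1])


def discretize_log_odds(pwm: PWM, granularity: float) -> np.ndarray:
    """Per-position integer score matrix: rint(log-odds / granularity)."""
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    return np.rint(pwm.log_odds() / granularity).astype(np.int64)


def score_distribution(pwm: PWM, granularity: float = 0.01) -> ScoreDistribution:
    """Exact distribution of the discretized score of a random background
    word of length L, by positionwise convolution."""
    iscores = discretize_log_odds(pwm, granularity)
    bg = pwm.background
    dist: dict[int, float] = {0: 1.0}
    for pos in range(pwm.length):
        nxt: dict[int, float] = {}
        for k, mass in dist.items():
            for b in range(4):
                if bg[b] == 0:
                    continue
                key = k + int(iscores[pos, b])
                nxt[key] = nxt.get(key, 0.0) + mass * bg[b]
        dist = nxt
    grid = np.array(sorted(dist), dtype=np.int64)
    pmf = np.array([dist[k] for k in grid])
    pmf = pmf / pmf.sum()  # guard accumulated rounding
    return ScoreDistribution(grid, pmf, granularity)


def pvalue_cutoff(dist: ScoreDistribution, alpha: float) -> float:
    """Minimal grid score s with P(score >= s) <= alpha, in log-odds units."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    sf = dist.sf
    attainable = sf <= alpha
    if not attainable.any():
        warnings.warn(
            f"alpha={alpha} below the minimal attainable p "
            f"({dist.min_pvalue():.3g}); returning the maximum support score"
        )
        return float(dist.grid[-1] * dist.granularity)
    idx = int(np.argmax(attainable))
    return float(dist.grid[idx] * dist.granularity)


@dataclass(frozen=True)
class ScanRegion:
    """The 3' CDS tail + 3'UTR of one transcript, with source spans
    recorded in 0-based half-open transcript coordinates."""

    gene_id: str
    sequence: str
    cds_span: tuple[int, int]
    utr_span: tuple[int, int]

    @property
    def length(self) -> int:
        return len(self.sequence)


def extract_scan_region(tx: TranscriptModel, cds_fraction: float = 0.25) -> ScanRegion:
    """Last ⌈cds_fraction × n_codons⌉ codons of the CDS plus the whole
    3'UTR. Codon-boundary aligned (ceiling rule) so frame semantics are
    preserved; an empty 3'UTR is allowed, an empty CDS is not."""
    if not 0 < cds_fraction <= 1:
        raise ValueError("cds_fraction must be in (0, 1]")
    if not tx.cds:
        raise ValueError(f"{tx.gene_id}: empty CDS")
    n_codons = tx.n_codons
    k = math.ceil(cds_fraction * n_codons)
    tail_start = (n_codons - k) * 3
    region = tx.cds[tail_start:] + tx.utr3
    cds_len = len(tx.cds)
    return ScanRegion(
        tx.gene_id,
        region,
        cds_span=(tail_start, cds_len),
        utr_span=(cds_len, cds_len + len(tx.utr3)),
    )


@dataclass(frozen=True)
class MotifHit:
    start: int  # 0-based offset within the scan region
    score: float  # log-odds, in granularity-rounded units
    pvalue: float
    hit_class: HitClass


@dataclass(frozen=True)
class MotifHitSet:
    gene_id: str
    hits: tuple[MotifHit, ...]
    region_length: int

    def __post_init__(self) -> None:
        for h in self.hits:
            if not 0 <= h.start <= self.region_length:
                raise ValueError(f"{self.gene_id}: hit at {h.start} outside region")
            if not 0 < h.pvalue < 1:
                raise ValueError(f"{self.gene_id}: p-value {h.pvalue} outside (0,1)")

    @property
    def n_significant(self) -> int:
        return sum(1 for h in self.hits if h.hit_class == "significant")

    def count(self, include_suboptimal: bool = True) -> int:
        return len(self.hits) if include_suboptimal else self.n_significant


def scan(
    region: ScanRegion | str,
    pwm: PWM,
    dist: ScoreDistribution | None = None,
    alphas: tuple[float, float] = (0.005, 0.01),
    merge_overlaps: bool = False,
    gene_id: str = "",
) -> MotifHitSet:
    """Score every sense-strand start offset; report offsets with
    p < alphas[1], classing those with p < alphas[0] as significant.

    Overlapping matches are each counted by default (per-position
    convention); ``merge_overlaps`` keeps only the best hit of any run of
    mutually overlapping hits, for sensitivity analysis. A region shorter
    than the motif yields an empty hit set, not an error.
    """
    alpha_sig, alpha_sub = alphas
    if alpha_sig > alpha_sub:
        raise ValueError("significant alpha must be <= suboptimal alpha")
    if isinstance(region, str):
        region = ScanRegion(gene_id or "region", canonical_nt(region), (0, 0), (0, len(region)))
    if dist is None:
        dist = score_distribution(pwm)
    seq = region.sequence
    L = pwm.length
    iscores = discretize_log_odds(pwm, dist.granularity)
    hits: list[MotifHit] = []
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        if "N" in window:
            continue
        k = int(sum(iscores[i, NT_INDEX[window[i]]] for i in range(L)))
        p = dist.pvalue(k)
        if p < alpha_sub:
            klass: HitClass = "significant" if p < alpha_sig else "suboptimal"
            hits.append(MotifHit(start, k * dist.granularity, p, klass))
    if merge_overlaps:
        hits = _merge_overlapping(hits, L)
    return MotifHitSet(region.gene_id, tuple(hits), region.length)


def _merge_overlapping(hits: list[MotifHit], L: int) -> list[MotifHit]:
    merged: list[MotifHit] = []
    cluster: list[MotifHit] = []
    for h in hits:
        if cluster and h.start >= cluster[-1].start + L:
            merged.append(max(cluster, key=lambda x: x.score))
            cluster = []
        cluster.append(h)
    if cluster:
        merged.append(max(cluster, key=lambda x: x.score))
    return merged


def site_density(hit_set: MotifHitSet, include_suboptimal: bool = True) -> float:
    """Reported hits per kilobase of scanned region."""
    if hit_set.region_length <= 0:
        raise ValueError(f"{hit_set.gene_id}: zero-length scan region")
    return hit_set.count(include_suboptimal) / (hit_set.region_length / 1000.0)


def frame_rarity_profile(
    motif_word: str,
    flank5: str,
    flank3: str,
    weights: WeightTable,
) -> dict[int, dict]:
    """Codon composition of a motif word read in each of the 3 frames.

    Frame f means f nucleotides of the motif complete an upstream codon;
    partial codons are completed from the flanks. Stop codons arising in a
    shifted frame are labelled "stop". Returns, per frame, the covering
    codons, their classes, and rare/common counts — showing how a frame
    shift of the same U-rich element can enrich rare or common codons.
    """
    word = canonical_nt(motif_word)
    if len(word) < 3:
        raise ValueError("motif word must be at least 3 nt")
    f5, f3 = canonical_nt(flank5), canonical_nt(flank3)
    profile: dict[int, dict] = {}
    for frame in range(3):
        if len(f5) < frame:
            raise ValueError(f"frame {frame}: 5' flank too short ({len(f5)} nt)")
        prefix = f5[len(f5) - frame :] if frame else ""
        stretch = prefix + word
        pad = (-len(stretch)) % 3
        if len(f3) < pad:
            raise ValueError(f"frame {frame}: 3' flank too short ({len(f3)} nt, need {pad})")
        stretch += f3[:pad]
        codons = [stretch[i : i + 3] for i in range(0, len(stretch), 3)]
        classes = []
        for c in codons:
            if GENETIC_CODE.get(c) == "*":
                classes.append("stop")
            elif "N" in c:
                classes.append("unknown")
            else:
                classes.append(codon_class(c, weights))
        profile[frame] = {
            "codons": codons,
            "classes": classes,
            "n_rare": classes.count("rare"),
            "n_common": classes.count("common"),
        }
    return profile
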