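"""Readers/writers and shared plumbing used by every analysis stage.

All sequence I/O goes through Biopython; tabular I/O through pandas. The
canonical nucleotide alphabet is DNA: U is converted to T on input (usage
tables and CDS FASTA are DNA-based). Coordinates in written reports are
1-based inclusive; internal arithmetic is 0-based half-open.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

VALID_NT = set("ACGTN")

logger = logging.getLogger("rarecode")


def get_logger(stage: str) -> logging.LoggerAdapter:
    """Stage-tagged logger writing to stderr."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(stage)s] %(levelname)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logging.LoggerAdapter(logger, {"stage": stage})


class FormatError(ValueError):
    """Malformed input file (bad FASTA, bad matrix, bad table schema)."""


def canonical_nt(sequence: str) -> str:
    """Uppercase, strip whitespace, convert RNA U to DNA T."""
    return "".join(sequence.split()).upper().replace("U", "T")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (DNA canonical alphabet)."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be nonempty")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - VALID_NT
        if bad:
            raise ValueError(f"{self.id}: illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript split into its CDS and (possibly empty) 3'UTR.

    ``complete`` marks a CDS asserted to begin with ATG and contain no
    internal stop codon; the invariants are only enforced when it is set.
    """

    gene_id: str
    cds: str
    utr3: str = ""
    complete: bool = False

    def __post_init__(self) -> None:
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {len(self.cds)} not divisible by 3")
        if self.complete:
            if not self.cds.startswith("ATG"):
                raise ValueError(f"{self.gene_id}: complete CDS must start with ATG")
            internal = [self.cds[i : i + 3] for i in range(0, len(self.cds) - 3, 3)]
            stops = {"TAA", "TAG", "TGA"}
            if any(c in stops for c in internal):
                raise ValueError(f"{self.gene_id}: internal stop codon in complete CDS")

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3


@dataclass
class RunConfig:
    """Pipeline-wide parameters; defaults follow the published procedure."""

    usage_table: str | None = None
    pwm: str | None = None
    p_significant: float = 0.005
    p_suboptimal: float = 0.01
    cds_scan_fraction: float = 0.25
    cai_bin_boundaries: tuple[float, float] = (0.68, 0.78)
    enrichment_top_quantile: float = 0.25
    enrichment_other_quantile: float = 0.60
    seed: int = 0
    out_dir: str = "."
    float_precision: int = 3

    def __post_init__(self) -> None:
        for p in (self.p_significant, self.p_suboptimal):
            if not 0 < p < 1:
                raise ValueError(f"p-value threshold {p} outside (0,1)")
        if self.p_significant > self.p_suboptimal:
            raise ValueError("significant threshold must be <= suboptimal threshold")
        if not 0 < self.cds_scan_fraction <= 1:
            raise ValueError("scan fraction must be in (0,1]")
        lo, hi = self.cai_bin_boundaries
        if not lo < hi:
            raise ValueError("CAI bin boundaries must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "cai_bin_boundaries" in data:
            data["cai_bin_boundaries"] = tuple(data["cai_bin_boundaries"])
        return cls(**data)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased, U→T).

    Raises FormatError with a line number for illegal characters.
    """
    records: list[SequenceRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise FormatError(f"{path}: {exc}") from exc
    for rec in parsed:
        seq = canonical_nt(str(rec.seq))
        bad = set(seq) - VALID_NT
        if bad:
            line = _find_offending_line(path, bad)
            raise FormatError(
                f"{path}: record {rec.id!r} contains illegal characters "
                f"{sorted(bad)} (near line {line})"
            )
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, rec.description, seq))
    return records


def _find_offending_line(path: str | Path, bad: set[str]) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if bad & set(canonical_nt(line)):
                return i
    return 0


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


#: schema entry: column name -> dtype ("str", "float", "int")
ColumnSpec = Mapping[str, str]

_DTYPES = {"str": str, "float": float, "int": "Int64"}


def read_table(path: str | Path, schema: ColumnSpec | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV with header, enforcing and typing required columns.

    Missing values are kept as NaN/NA (flagged, never dropped). A required
    column that is absent raises FormatError; a cell that cannot be parsed
    to the requested type raises FormatError naming the 1-based data row.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        for col, kind in schema.items():
            if kind == "str":
                continue
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & converted.isna()
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise FormatError(
                    f"{path}: column {col!r} row {row}: "
                    f"cannot parse {df[col][bad.idxmax()]!r} as {kind}"
                )
            df[col] = converted.astype(_DTYPES[kind]) if kind == "int" else converted
    return df


def write_report(
    dataset: pd.DataFrame,
    path: str | Path,
    float_precision: int = 3,
    sort_by: Sequence[str] | None = None,
    allow_empty: bool = False,
) -> None:
    """Write a TSV report: header always present, fixed float precision,
    deterministic row order (by ``sort_by`` columns, else by gene id /
    position columns when present)."""
    if dataset.empty and not allow_empty:
        raise ValueError(f"refusing to write empty report to {path} (pass allow_empty)")
    df = dataset.copy()
    if sort_by is None:
        sort_by = [c for c in ("gene_id", "gene", "start_1based", "position") if c in df.columns]
    if sort_by and not df.empty:
        df = df.sort_values(list(sort_by), kind="mergesort")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_precision}f")
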