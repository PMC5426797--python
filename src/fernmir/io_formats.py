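"""Readers/writers for the external formats and the packaged reference tables.

Sequences are held internally in the DNA alphabet (U is mapped to T on input and the
original alphabet is recorded), because mature miRNA tables conventionally print the
T-form of the sequenced cDNA.  Writers can render either alphabet.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Optional

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .phylo import PresenceMatrix


class ParseError(ValueError):
    pass


class IntegrityError(ValueError):
    pass


def normalize_sequence(seq: str) -> tuple[str, bool]:
    """Uppercase and map U->T; returns (dna_sequence, was_rna)."""
    s = seq.upper()
    was_rna = "U" in s
    return s.replace("U", "T"), was_rna


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class SmallRNARead:
    """A sequencing read or a collapsed unique sequence with its read count."""

    sequence: str
    count: int = 1
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError("empty read sequence")
        if self.count < 1:
            raise ParseError(f"read count must be >= 1, got {self.count}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ParseError("quality string length does not match sequence length")


@dataclass
class ReferenceMiRNA:
    """A miRBase-style mature reference miRNA a sequenced tag can be assigned to."""

    id: str
    species_prefix: str
    family_number: str
    paralog_letter: str
    arm: str  # "5p", "3p" or "unspecified"
    sequence: str
    high_confidence: bool = True

    @classmethod
    def from_id(cls, mirbase_id: str, sequence: str, high_confidence: bool = True):
        sp, fam, letter, arm = parse_mirbase_id(mirbase_id)
        seq, _ = normalize_sequence(sequence)
        if not 18 <= len(seq) <= 26:
            raise ParseError(
                f"reference {mirbase_id}: mature length {len(seq)} outside [18, 26]"
            )
        return cls(mirbase_id, sp, fam, letter, arm, seq, high_confidence)

    @property
    def family(self) -> str:
        return f"miR{self.family_number}"


@dataclass
class Transcript:
    id: str
    sequence: str
    cds: Optional[tuple[int, int]] = None  # 0-based half-open

    def __post_init__(self) -> None:
        if self.cds is not None:
            s, e = self.cds
            if not (0 <= s < e <= len(self.sequence)):
                raise ParseError(
                    f"transcript {self.id}: CDS [{s}, {e}) outside [0, {len(self.sequence)})"
                )


class FastaResult(NamedTuple):
    records: list[tuple[str, str]]
    rna_alphabet: bool


# FASTA is read with a small line-level scanner (rather than a library parser) so that
# malformed input is reported with its line number, which the library parsers drop.
def read_fasta(path: str | Path) -> FastaResult:
    records: list[tuple[str, str]] = []
    rna = False
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        nonlocal rna
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}: empty sequence for record at line {header_line}")
        seq, was_rna = normalize_sequence(seq)
        rna = rna or was_rna
        records.append((header, seq))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ParseError(f"{path}: malformed FASTA header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}: sequence before any FASTA header at line {lineno}"
                    )
                chunks.append(line)
        flush()
    return FastaResult(records, rna)


def write_fasta(path: str | Path, records: list[tuple[str, str]], alphabet: str = "dna") -> None:
    if alphabet not in ("dna", "rna"):
        raise ValueError(f"alphabet must be 'dna' or 'rna', got {alphabet!r}")
    with open(path, "w") as fh:
        for rec_id, seq in records:
            out = to_rna(seq) if alphabet == "rna" else seq.upper().replace("U", "T")
            fh.write(f">{rec_id}\n{out}\n")


def read_fastq(path: str | Path) -> list[SmallRNARead]:
    """Read 4-line FASTQ records; each read carries count=1 and its quality string."""
    reads: list[SmallRNARead] = []
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise ParseError(
                    f"{path}: malformed FASTQ at record index {len(reads)}: {exc}"
                ) from exc
            seq, _ = normalize_sequence(seq)
            if len(qual) != len(seq):
                raise ParseError(
                    f"{path}: quality length mismatch at record index {len(reads)}"
                )
            reads.append(SmallRNARead(seq, count=1, quality=qual))
    return reads


_COLLAPSED_COUNT = re.compile(r"^(?P<name>.*?)[_-](?P<count>\d+)$")


def read_collapsed(path: str | Path) -> list[SmallRNARead]:
    """Read pre-collapsed FASTA where the header encodes the count (e.g. ``>tag_17``)."""
    reads = []
    for rec_id, seq in read_fasta(path).records:
        m = _COLLAPSED_COUNT.match(rec_id)
        if not m:
            raise ParseError(
                f"{path}: collapsed-FASTA header {rec_id!r} carries no trailing count"
            )
        reads.append(SmallRNARead(seq, count=int(m.group("count"))))
    return reads


# Accepts the dialects "ath-miR157a-5p", "ath-miR157a_5p" and "ath-miR157a 5p".
_MIRBASE_ID = re.compile(
    r"^(?P<sp>[A-Za-z]{3,4})-miR(?P<num>\d+)(?P<letter>[a-z]*)"
    r"(?:[-_ ](?P<arm>[53]p))?$",
    re.IGNORECASE,
)


def parse_mirbase_id(mirbase_id: str) -> tuple[str, str, str, str]:
    """Split e.g. ``ath-miR157a-5p`` into (species, family number, paralog letter, arm)."""
    m = _MIRBASE_ID.match(mirbase_id.strip())
    if not m:
        raise ParseError(f"not a miRBase-style mature miRNA id: {mirbase_id!r}")
    arm = (m.group("arm") or "unspecified").lower()
    return m.group("sp").lower(), m.group("num"), m.group("letter").lower(), arm


def format_mirbase_id(
    species_prefix: str, family_number: str, paralog_letter: str = "", arm: str = "unspecified"
) -> str:
    """Canonical hyphenated form, the inverse of :func:`parse_mirbase_id`."""
    base = f"{species_prefix}-miR{family_number}{paralog_letter}"
    return base if arm == "unspecified" else f"{base}-{arm}"


def read_reference_fasta(
    path: str | Path, high_confidence: Optional[dict[str, bool]] = None
) -> list[ReferenceMiRNA]:
    """Load mature reference miRNAs from FASTA with miRBase-style record ids.

    ``high_confidence`` maps id -> flag; ids absent from the map default to True
    (the repository cannot ship the community confidence re-evaluation).
    """
    refs = []
    for rec_id, seq in read_fasta(path).records:
        hc = True if high_confidence is None else high_confidence.get(rec_id, True)
        refs.append(ReferenceMiRNA.from_id(rec_id, seq, hc))
    return refs


def read_high_confidence_table(path: str | Path) -> dict[str, bool]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        str(r.iloc[0]): bool(int(r.iloc[1])) for _, r in df.iterrows()
    }


def read_cds_table(path: str | Path) -> dict[str, tuple[int, int]]:
    """TSV of (transcript_id, cds_start, cds_end), 0-based half-open."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        str(r.iloc[0]): (int(r.iloc[1]), int(r.iloc[2])) for _, r in df.iterrows()
    }


def read_transcripts(
    path: str | Path, cds: Optional[dict[str, tuple[int, int]]] = None
) -> list[Transcript]:
    cds = cds or {}
    return [
        Transcript(rec_id, seq, cds.get(rec_id)) for rec_id, seq in read_fasta(path).records
    ]


@dataclass
class FixtureTables:
    """The packaged reference tables: mature variants, conserved targets, the
    family x taxon presence grid and the land-plant cladogram."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    fig3_matrix: PresenceMatrix
    fig1_tree: str


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("fernmir").joinpath("fixtures", name)))


def load_fixtures() -> FixtureTables:
    counts = pd.read_csv(
        _fixture_path("expected_counts.tsv"), sep="\t", comment="#"
    ).set_index("key")["value"]

    table1 = pd.read_csv(_fixture_path("table1.tsv"), sep="\t", comment="#")
    table2 = pd.read_csv(_fixture_path("table2.tsv"), sep="\t", comment="#")
    matrix = PresenceMatrix.from_tsv(_fixture_path("fig3_matrix.tsv"))
    tree = _fixture_path("fig1_tree.nwk").read_text().strip()

    checks = {
        "table1_rows": len(table1),
        "table1_families": table1["family"].nunique(),
        "table2_rows": len(table2),
        "table2_families": table2["family"].nunique(),
        "matrix_families": len(matrix.families),
        "matrix_taxa": len(matrix.taxa),
    }
    for key, got in checks.items():
        if got != int(counts[key]):
            raise IntegrityError(
                f"fixture integrity: {key} = {got}, expected {int(counts[key])}"
            )
    missing = set(table1["family"]) - set(matrix.families)
    if missing:
        raise IntegrityError(f"families missing from presence matrix: {sorted(missing)}")
    return FixtureTables(table1, table2, matrix, tree)
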