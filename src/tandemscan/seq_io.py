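"""FASTA input/output and base-composition statistics.

Sequences are normalized on input to the alphabet {A, C, G, T, N}:
lowercase is upper-cased and every IUPAC ambiguity code other than N is
mapped to N, since the analysis only distinguishes known bases from
unknown ones.  All densities downstream are computed per *effective*
(non-N) base pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

_NORMALIZE = {c: (c if c in "ACGTN" else "N") for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"}
_NORM_TABLE = str.maketrans(
    "".join(_NORMALIZE) + "".join(_NORMALIZE).lower(),
    "".join(_NORMALIZE.values()) * 2,
)

PathLike = Union[str, Path]


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input; carries a line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class SequenceRecord:
    """An uppercase nucleotide sequence over {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self):
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise ValueError(f"non-normalized residues: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> str:
    """Uppercase and collapse ambiguity codes (everything but ACGT) to N."""
    out = raw.translate(_NORM_TABLE)
    bad = set(out) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
    return out


def _validate_fasta_layout(handle: TextIO) -> None:
    """Reject structurally broken FASTA with a line-numbered error."""
    saw_header = False
    header_line = 0
    body = 0
    for i, line in enumerate(handle, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if saw_header and body == 0:
                raise FastaParseError("record without sequence", header_line)
            if stripped == ">":
                raise FastaParseError("empty FASTA header", i)
            saw_header = True
            header_line = i
            body = 0
        else:
            if not saw_header:
                raise FastaParseError("sequence data before any '>' header", i)
            body += len(stripped)
    if saw_header and body == 0:
        raise FastaParseError("record without sequence", header_line)
    handle.seek(0)


def read_fasta(path_or_handle: Union[PathLike, TextIO]) -> list[SequenceRecord]:
    """Read all records from a FASTA file, normalized, order preserved."""
    if hasattr(path_or_handle, "read"):
        handle = path_or_handle
        _validate_fasta_layout(handle)
        records = list(SeqIO.parse(handle, "fasta"))
    else:
        with open(path_or_handle) as fh:
            _validate_fasta_layout(fh)
            records = list(SeqIO.parse(fh, "fasta"))
    return [SequenceRecord(r.id, normalize_residues(str(r.seq))) for r in records]


def read_fasta_str(text: str) -> list[SequenceRecord]:
    return read_fasta(StringIO(text))


def write_fasta(records: Iterable[SequenceRecord], path_or_handle) -> None:
    """Write records wrapped at 60 columns (fixed, for byte-stable output)."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, path_or_handle, "fasta")


def effective_length(rec: Union[SequenceRecord, str]) -> int:
    """Number of non-N residues — the denominator of every density."""
    residues = rec if isinstance(rec, str) else rec.residues
    return len(residues) - residues.count("N")


@dataclass(frozen=True)
class CompositionStats:
    """Single-base and di/trinucleotide composition of one sequence.

    Ratios with an undefined denominator are NaN ("missing"), never 0.
    ``corrected_cpg`` and ``corrected_cpnpg`` are observed/expected
    normalizations: observed CpG (or CpNpG, any middle base) count times
    effective length over (#C * #G).  Windows containing an N are
    skipped.
    """

    a: int
    c: int
    g: int
    t: int
    n: int
    length: int
    effective_length: int
    cg_content: float
    at_ratio: float
    cg_ratio: float
    cpg_count: int
    cpnpg_count: int
    corrected_cpg: float
    corrected_cpnpg: float


def _ratio(num: float, den: float) -> float:
    return num / den if den else math.nan


def composition(rec: Union[SequenceRecord, str]) -> CompositionStats:
    s = rec if isinstance(rec, str) else rec.residues
    counts = {b: s.count(b) for b in "ACGTN"}
    eff = len(s) - counts["N"]

    cpg = 0
    cpnpg = 0
    for i in range(len(s) - 1):
        if s[i] == "C" and s[i + 1] == "G":
            cpg += 1
    for i in range(len(s) - 2):
        if s[i] == "C" and s[i + 2] == "G" and s[i + 1] != "N":
            cpnpg += 1

    c, g = counts["C"], counts["G"]
    return CompositionStats(
        a=counts["A"],
        c=c,
        g=g,
        t=counts["T"],
        n=counts["N"],
        length=len(s),
        effective_length=eff,
        cg_content=_ratio(c + g, eff),
        at_ratio=_ratio(counts["A"], counts["T"]),
        cg_ratio=_ratio(c, g),
        cpg_count=cpg,
        cpnpg_count=cpnpg,
        corrected_cpg=_ratio(cpg * eff, c * g),
        corrected_cpnpg=_ratio(cpnpg * eff, c * g),
    )
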