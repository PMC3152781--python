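"""Genomic-region stratification from GFF annotations.

Gene models (one per annotated transcript) are read from GFF, cleaned
deterministically, and used to partition each sequence into CDS,
intron, 5'UTR, 3'UTR, exon and intergenic fragments:

* overlapping gene models on the same strand: the one with the longer
  genomic span is removed, iterated until stable (equal spans: the
  rightmost is removed);
* overlapping exons or CDS features within one model: likewise the
  longer feature is removed;
* introns are the gaps between a model's deduplicated exons;
* UTRs are inferred from start/stop codon positions where annotated —
  exonic sequence upstream of the start codon is 5'UTR and downstream
  of the stop codon is 3'UTR, in transcription direction;
* intergenic regions are the complement of all (deduplicated) gene
  spans and carry no strand.

Fragments of stranded kinds carry the *sense strand*: minus-strand
fragments are reverse-complemented on extraction, so repeat motifs read
from them are the motifs the transcription machinery sees.  Exon
fragments are produced but excluded from default reports, their repeat
content being the union of CDS and UTR content.

Coordinates are GFF 1-based inclusive on disk and 0-based half-open in
memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import gffutils

from .seq_io import SequenceRecord, effective_length
from .units import reverse_complement

Interval = tuple[int, int]  # 0-based half-open

REGION_KINDS = ("CDS", "intron", "five_prime_UTR", "three_prime_UTR", "intergenic", "exon")
STRANDED_KINDS = ("CDS", "intron", "five_prime_UTR", "three_prime_UTR")
DEFAULT_REPORT_KINDS = ("CDS", "intron", "five_prime_UTR", "three_prime_UTR", "intergenic")


class GffParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class GeneModel:
    """One gene model (transcript): exons, CDS and codon annotations."""

    id: str
    sequence_id: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds_segments: list[Interval] = field(default_factory=list)
    start_codon: Interval | None = None
    stop_codon: Interval | None = None
    flagged: bool = False  # inconsistent annotation (codon outside exons)

    @property
    def span(self) -> Interval:
        feats = self.exons + self.cds_segments
        if not feats:
            raise ValueError(f"gene model {self.id} has no features")
        return min(a for a, _ in feats), max(b for _, b in feats)

    @property
    def span_length(self) -> int:
        a, b = self.span
        return b - a


@dataclass(frozen=True)
class RegionFragment:
    """A genomic interval of one region kind, with sense-strand sequence."""

    kind: str
    sequence_id: str
    start: int
    end: int
    strand: str  # '+', '-' or '.' for strandless (intergenic)
    sequence: str
    gene_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def fragment_id(self) -> str:
        return f"{self.sequence_id}:{self.start + 1}-{self.end}({self.strand}):{self.kind}"


def _validate_gff_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 8:
            raise GffParseError(
                f"expected at least 8 tab-separated columns, found {len(fields)}", lineno
            )
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise GffParseError("non-integer coordinates", lineno) from None
        if end < start:
            raise GffParseError(f"end < start ({end} < {start})", lineno)
        if fields[6] not in "+-.?":
            raise GffParseError(f"unknown strand symbol {fields[6]!r}", lineno)


_MODEL_FEATURES = {"exon", "CDS", "start_codon", "stop_codon"}


def parse_gff(path_or_text: Union[str, Path]) -> list[GeneModel]:
    """Read gene models from a GFF file (GFF3 Parent= links or GTF-style
    gene_id/transcript_id groups, both handled by gffutils).

    Every transcript-level feature group becomes one GeneModel; exons or
    CDS parented directly to a gene (no mRNA level) form a model named
    after the gene.  Malformed lines raise GffParseError with the line
    number.
    """
    p = Path(path_or_text)
    text = p.read_text()
    _validate_gff_lines(text)
    db = gffutils.create_db(
        str(p),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: dict[str, GeneModel] = {}

    def model_for(key: str, seqid: str, strand: str) -> GeneModel:
        if key not in models:
            models[key] = GeneModel(id=key, sequence_id=seqid, strand=strand)
        return models[key]

    for feat in db.all_features():
        if feat.featuretype not in _MODEL_FEATURES:
            continue
        parents = feat.attributes.get("Parent") or feat.attributes.get(
            "transcript_id"
        )
        key = parents[0] if parents else (feat.attributes.get("gene_id", [feat.seqid])[0])
        m = model_for(key, feat.seqid, feat.strand)
        if m.sequence_id != feat.seqid or m.strand != feat.strand:
            raise GffParseError(f"gene model {key} mixes sequences or strands")
        iv = (feat.start - 1, feat.end)  # to 0-based half-open
        if feat.featuretype == "exon":
            m.exons.append(iv)
        elif feat.featuretype == "CDS":
            m.cds_segments.append(iv)
        elif feat.featuretype == "start_codon":
            m.start_codon = iv
        else:
            m.stop_codon = iv
    out = list(models.values())
    for m in out:
        m.exons.sort()
        m.cds_segments.sort()
        if not m.exons and m.cds_segments:
            # exon-less catalogues: treat CDS segments as the exons too
            m.exons = list(m.cds_segments)
    out.sort(key=lambda m: (m.sequence_id, m.span[0], m.span[1], m.id))
    return out


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def dedup_gene_models(models: Sequence[GeneModel]) -> list[GeneModel]:
    """Remove the longer model of every same-strand overlapping pair,
    re-scanning until stable; equal spans drop the rightmost."""
    pool = sorted(models, key=lambda m: (m.sequence_id, m.span[0], m.span[1], m.id))
    changed = True
    while changed:
        changed = False
        for i in range(len(pool)):
            mi = pool[i]
            for j in range(i + 1, len(pool)):
                mj = pool[j]
                if mj.sequence_id != mi.sequence_id or mj.span[0] >= mi.span[1]:
                    break
                if mj.strand != mi.strand:
                    continue
                if _overlaps(mi.span, mj.span):
                    li, lj = mi.span_length, mj.span_length
                    # remove the longer; ties remove the rightmost (j,
                    # which starts later or sorts later)
                    victim = i if li > lj else j
                    del pool[victim]
                    changed = True
                    break
            if changed:
                break
    return pool


def _dedup_intervals(ivs: list[Interval]) -> list[Interval]:
    pool = sorted(ivs)
    changed = True
    while changed:
        changed = False
        for i in range(len(pool) - 1):
            a, b = pool[i], pool[i + 1]
            if _overlaps(a, b):
                la, lb = a[1] - a[0], b[1] - b[0]
                del pool[i if la > lb else i + 1]
                changed = True
                break
    return pool


def dedup_features(model: GeneModel) -> GeneModel:
    """Remove the longer of any two overlapping exons (and CDS features)
    of one gene model; equal lengths keep the leftmost."""
    return replace(
        model,
        exons=_dedup_intervals(model.exons),
        cds_segments=_dedup_intervals(model.cds_segments),
    )


def infer_introns(model: GeneModel) -> list[Interval]:
    """Gaps strictly between consecutive (deduplicated) exons."""
    out = []
    exons = sorted(model.exons)
    for (_, e1), (s2, _) in zip(exons, exons[1:]):
        if s2 > e1:
            out.append((e1, s2))
    return out


def infer_utrs(model: GeneModel) -> tuple[list[Interval], list[Interval]]:
    """(5'UTR, 3'UTR) intervals inferred from codon annotations.

    Returns empty lists when codons are not annotated; flags the model
    and returns empty lists when a codon lies outside all exons.
    """
    if model.start_codon is None and model.stop_codon is None:
        return [], []

    def _inside_exons(iv: Interval) -> bool:
        return any(a <= iv[0] and iv[1] <= b for a, b in model.exons)

    for codon in (model.start_codon, model.stop_codon):
        if codon is not None and not _inside_exons(codon):
            model.flagged = True
            return [], []

    def _exonic_before(limit: int) -> list[Interval]:
        return [(a, min(b, limit)) for a, b in model.exons if a < limit]

    def _exonic_after(limit: int) -> list[Interval]:
        return [(max(a, limit), b) for a, b in model.exons if b > limit]

    five: list[Interval] = []
    three: list[Interval] = []
    if model.strand == "+":
        if model.start_codon is not None:
            five = _exonic_before(model.start_codon[0])
        if model.stop_codon is not None:
            three = _exonic_after(model.stop_codon[1])
    else:
        if model.start_codon is not None:
            five = _exonic_after(model.start_codon[1])
        if model.stop_codon is not None:
            three = _exonic_before(model.stop_codon[0])
    return five, three


def infer_intergenic(
    sequence_lengths: Mapping[str, int], models: Sequence[GeneModel]
) -> dict[str, list[Interval]]:
    """Complement of the union of gene spans, per sequence."""
    spans: dict[str, list[Interval]] = {sid: [] for sid in sequence_lengths}
    for m in models:
        spans.setdefault(m.sequence_id, []).append(m.span)
    out: dict[str, list[Interval]] = {}
    for sid, length in sequence_lengths.items():
        ivs = sorted(spans.get(sid, []))
        merged: list[Interval] = []
        for iv in ivs:
            if merged and iv[0] <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], iv[1]))
            else:
                merged.append(iv)
        gaps = []
        prev = 0
        for a, b in merged:
            if a > prev:
                gaps.append((prev, a))
            prev = max(prev, b)
        if prev < length:
            gaps.append((prev, length))
        out[sid] = gaps
    return out


def extract_regions(
    genome: Sequence[SequenceRecord],
    models: Sequence[GeneModel],
    dedup: bool = True,
) -> dict[str, list[RegionFragment]]:
    """Split a genome into region fragments keyed by kind.

    Stranded kinds carry sense-strand sequence (minus-strand fragments
    reverse-complemented); intergenic fragments are strandless.  Exon
    fragments are returned under "exon" but are conventionally excluded
    from combined reports.
    """
    seqs = {r.id: r.residues for r in genome}
    if dedup:
        models = [dedup_features(m) for m in dedup_gene_models(models)]
    out: dict[str, list[RegionFragment]] = {k: [] for k in REGION_KINDS}

    def _cut(sid: str, iv: Interval, model: GeneModel | None) -> str:
        s = seqs[sid]
        if iv[0] < 0 or iv[1] > len(s):
            owner = model.id if model else "?"
            raise ValueError(
                f"interval {iv} of model {owner} exceeds bounds of sequence {sid}"
            )
        return s[iv[0] : iv[1]]

    def _emit(kind: str, sid: str, iv: Interval, strand: str, model: GeneModel | None):
        if iv[1] <= iv[0]:
            return
        frag = _cut(sid, iv, model)
        if strand == "-" and kind in STRANDED_KINDS:
            frag = reverse_complement(frag)
        out[kind].append(
            RegionFragment(
                kind=kind,
                sequence_id=sid,
                start=iv[0],
                end=iv[1],
                strand=strand if kind in STRANDED_KINDS or kind == "exon" else ".",
                sequence=frag,
                gene_id=model.id if model else None,
            )
        )

    for m in models:
        if m.sequence_id not in seqs:
            raise ValueError(f"gene model {m.id} references unknown sequence {m.sequence_id}")
        for iv in m.cds_segments:
            _emit("CDS", m.sequence_id, iv, m.strand, m)
        for iv in m.exons:
            _emit("exon", m.sequence_id, iv, m.strand, m)
        for iv in infer_introns(m):
            _emit("intron", m.sequence_id, iv, m.strand, m)
        five, three = infer_utrs(m)
        for iv in five:
            _emit("five_prime_UTR", m.sequence_id, iv, m.strand, m)
        for iv in three:
            _emit("three_prime_UTR", m.sequence_id, iv, m.strand, m)
    lengths = {r.id: len(r.residues) for r in genome}
    for sid, gaps in infer_intergenic(lengths, models).items():
        for iv in gaps:
            _emit("intergenic", sid, iv, ".", None)
    return out


def region_effective_lengths(
    fragments: Mapping[str, Sequence[RegionFragment]]
) -> dict[str, int]:
    return {
        kind: sum(effective_length(f.sequence) for f in frags)
        for kind, frags in fragments.items()
    }


def fragments_to_records(frags: Iterable[RegionFragment]) -> list[SequenceRecord]:
    """Region fragments as sequence records, ready for repeat detection."""
    return [SequenceRecord(f.fragment_id, f.sequence) for f in frags]
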