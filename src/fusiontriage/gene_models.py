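"""Transcript models and coordinate arithmetic.

All genomic coordinates are 0-based, half-open intervals on a named
chromosome with an explicit strand.  Transcript coordinates are nucleotide
offsets from the transcript 5' end (0-based, half-open), i.e. cumulative
exonic position in splicing order.  GTF input (1-based, inclusive) is
converted on read; BED12 input is already 0-based half-open.

Exons of a :class:`TranscriptModel` are stored in transcript (5'->3')
orientation, so ``exons[0]`` is the 5'-most exon regardless of genomic
strand.  Exon indices are 0-based internally; every user-facing surface
(screened-candidate tables, fusion calls, CLI output) reports them 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gffutils
from intervaltree import IntervalTree

__all__ = [
    "RTK_GENES",
    "GenomicInterval",
    "TranscriptModel",
    "GeneAnnotation",
    "AnnotationError",
    "load_annotation",
    "load_domain_table",
]

#: Receptor tyrosine kinase genes whose fusions the triage targets.  These
#: twelve are recurrent, druggable fusion drivers (imatinib for ABL1,
#: crizotinib/entrectinib for ALK and ROS1, larotrectinib for NTRK1-3,
#: selpercatinib for RET, FGFR and ERBB2 inhibitors for the rest).
RTK_GENES = frozenset(
    {
        "ABL1", "ALK", "ERBB2",
        "FGFR1", "FGFR2", "FGFR3", "FGFR4",
        "NTRK1", "NTRK2", "NTRK3",
        "RET", "ROS1",
    }
)

NOT_EXONIC = None  # sentinel returned for intronic / out-of-range positions


class AnnotationError(ValueError):
    """Raised for malformed annotation input or inconsistent domain tables."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class TranscriptModel:
    """One transcript: ordered exons, optional CDS and kinase-domain interval.

    Parameters
    ----------
    gene_symbol:
        HGNC symbol of the parent gene.
    transcript_id:
        Unique transcript identifier (e.g. Ensembl ``ENST...``).
    exons:
        Exons in transcript (5'->3') orientation.  For minus-strand genes
        this is descending genomic order.
    cds_start, cds_end:
        CDS bounds in transcript coordinates (nt, 0-based half-open), or
        ``None`` for non-coding transcripts.
    tk_domain:
        Tyrosine-kinase domain as a ``(start, end)`` transcript-coordinate
        interval, or ``None`` when not annotated/applicable.
    """

    gene_symbol: str
    transcript_id: str
    exons: list[GenomicInterval]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    tk_domain: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons span chromosomes/strands")
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        # enforce transcript orientation
        expected = ordered if self.strand == "+" else ordered[::-1]
        if self.exons != expected:
            raise ValueError(
                f"{self.transcript_id}: exons not in transcript (5'->3') order"
            )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: partial CDS bounds")
        if self.cds_start is not None:
            if not (0 <= self.cds_start < self.cds_end <= self.length):
                raise ValueError(f"{self.transcript_id}: CDS outside transcript")
        if self.tk_domain is not None:
            s, e = self.tk_domain
            if not (0 <= s < e <= self.length):
                raise AnnotationError(
                    f"{self.transcript_id}: tk_domain [{s}, {e}) outside "
                    f"transcript of length {self.length}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_lengths(self) -> list[int]:
        return [len(e) for e in self.exons]

    # -- coordinate arithmetic -------------------------------------------

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Map a genomic position to its transcript coordinate.

        Returns the cumulative exonic offset in transcript orientation, or
        ``None`` when ``pos`` is intronic or outside the transcript.
        """
        offset = 0
        for exon in self.exons:
            if exon.start <= pos < exon.end:
                if self.strand == "+":
                    return offset + (pos - exon.start)
                return offset + (exon.end - 1 - pos)
            offset += len(exon)
        return NOT_EXONIC

    def transcript_to_genomic(self, tpos: int) -> int:
        """Inverse of :meth:`genomic_to_transcript` for 0 <= tpos < length."""
        if not 0 <= tpos < self.length:
            raise ValueError(f"tpos {tpos} outside [0, {self.length})")
        offset = tpos
        for exon in self.exons:
            if offset < len(exon):
                if self.strand == "+":
                    return exon.start + offset
                return exon.end - 1 - offset
            offset -= len(exon)
        raise AssertionError("unreachable")

    def phase_at(self, tpos: int) -> Optional[int]:
        """Reading-frame phase at a transcript position.

        ``(tpos - cds_start) mod 3`` when the position lies within the CDS
        (closed interval, so ``phase_at(cds_end)`` is the CDS length mod 3);
        ``None`` for non-coding transcripts or UTR positions.
        """
        if not 0 <= tpos <= self.length:
            raise ValueError(f"tpos {tpos} outside [0, {self.length}]")
        if self.cds_start is None:
            return None
        if self.cds_start <= tpos <= self.cds_end:
            return (tpos - self.cds_start) % 3
        return None

    def exon_index_at(self, tpos: int) -> int:
        """0-based index of the exon containing transcript position tpos."""
        if not 0 <= tpos < self.length:
            raise ValueError(f"tpos {tpos} outside [0, {self.length})")
        offset = tpos
        for i, exon in enumerate(self.exons):
            if offset < len(exon):
                return i
            offset -= len(exon)
        raise AssertionError("unreachable")

    def exon_boundaries(self) -> list[int]:
        """Cumulative transcript coordinates of exon 3' ends (len n_exons)."""
        out, acc = [], 0
        for exon in self.exons:
            acc += len(exon)
            out.append(acc)
        return out


class GeneAnnotation:
    """A collection of transcript models indexed by id, gene and position."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.by_gene: dict[str, list[TranscriptModel]] = {}
        self._trees: dict[str, IntervalTree] = {}
        self.rtk_genes = RTK_GENES
        for tx in transcripts:
            self.add(tx)

    def add(self, tx: TranscriptModel) -> None:
        if tx.transcript_id in self.transcripts:
            raise AnnotationError(f"duplicate transcript_id {tx.transcript_id}")
        self.transcripts[tx.transcript_id] = tx
        self.by_gene.setdefault(tx.gene_symbol, []).append(tx)
        tree = self._trees.setdefault(tx.chrom, IntervalTree())
        for i, exon in enumerate(tx.exons):
            tree[exon.start:exon.end] = (tx.transcript_id, i)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def get(self, transcript_id: str) -> TranscriptModel:
        try:
            return self.transcripts[transcript_id]
        except KeyError:
            raise KeyError(f"unknown transcript {transcript_id!r}") from None

    def gene_of(self, transcript_id: str) -> str:
        return self.get(transcript_id).gene_symbol

    def is_rtk(self, gene_symbol: str) -> bool:
        return gene_symbol.upper() in self.rtk_genes

    def transcripts_overlapping(
        self, chrom: str, start: int, end: int
    ) -> list[TranscriptModel]:
        """Transcripts with >=1 exon overlapping [start, end) on chrom."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        ids = {iv.data[0] for iv in tree.overlap(start, end)}
        return [self.transcripts[t] for t in sorted(ids)]


# -- parsing -------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _check_lines(path: Path, min_fields: int, comment: str = "#") -> None:
    """Cheap structural pre-validation so errors can name the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(comment):
                continue
            if len(line.rstrip("\n").split("\t")) < min_fields:
                raise AnnotationError(
                    f"{path}: malformed line {lineno} "
                    f"(expected >={min_fields} tab-separated fields)"
                )


def _load_gtf(path: Path) -> list[TranscriptModel]:
    _check_lines(path, 9)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    genes: dict[str, str] = {}
    for ftype, store in (("exon", exons), ("CDS", cds)):
        for feat in db.features_of_type(ftype):
            tid = feat.attributes["transcript_id"][0]
            store.setdefault(tid, []).append(feat)
            name = feat.attributes.get("gene_name") or feat.attributes.get("gene_id")
            if name:
                genes.setdefault(tid, name[0])
    models = []
    for tid, feats in exons.items():
        strand = feats[0].strand
        ivs = sorted(
            (
                GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
                for f in feats
            ),
            key=lambda e: e.start,
        )
        if strand == "-":
            ivs = ivs[::-1]
        model = TranscriptModel(genes.get(tid, tid), tid, ivs)
        if tid in cds:
            tpos = []
            for f in cds[tid]:
                for g in (f.start - 1, f.end - 1):  # 5'- and 3'-most CDS bases
                    t = model.genomic_to_transcript(g)
                    if t is None:
                        raise AnnotationError(
                            f"{tid}: CDS base {f.seqid}:{g} not exonic"
                        )
                    tpos.append(t)
            model.cds_start, model.cds_end = min(tpos), max(tpos) + 1
            model.__post_init__()  # re-validate with CDS set
        models.append(model)
    return models


def _load_bed12(path: Path) -> list[TranscriptModel]:
    """BED12: one transcript per line; name is ``gene|transcript`` or a
    bare id used for both."""
    _check_lines(path, 12, comment="track")
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
                thick_start, thick_end = int(f[6]), int(f[7])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except (ValueError, IndexError) as exc:
                raise AnnotationError(f"{path}: malformed line {lineno}: {exc}")
            gene, _, tid = name.partition("|")
            tid = tid or name
            ivs = [
                GenomicInterval(chrom, start + s, start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
            ivs.sort(key=lambda e: e.start)
            if strand == "-":
                ivs = ivs[::-1]
            model = TranscriptModel(gene, tid, ivs)
            if thick_end > thick_start:
                tpos = [
                    t
                    for g in (thick_start, thick_end - 1)
                    if (t := model.genomic_to_transcript(g)) is not None
                ]
                if len(tpos) != 2:
                    raise AnnotationError(
                        f"{path}: line {lineno}: thickStart/thickEnd not exonic"
                    )
                model.cds_start, model.cds_end = min(tpos), max(tpos) + 1
                model.__post_init__()
            models.append(model)
    return models


def load_domain_table(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a kinase-domain table: transcript_id, tk_start, tk_end (TSV).

    Coordinates are transcript nucleotides, 0-based half-open.
    """
    path = Path(path)
    out: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[0] == "transcript_id":  # header
                continue
            if len(f) < 3:
                raise AnnotationError(f"{path}: malformed line {lineno}")
            try:
                out[f[0]] = (int(f[1]), int(f[2]))
            except ValueError as exc:
                raise AnnotationError(f"{path}: malformed line {lineno}: {exc}")
    return out


def load_annotation(
    path: str | Path, domain_table: str | Path | None = None
) -> GeneAnnotation:
    """Load transcript annotation (GTF or BED12) plus optional TK domains.

    The format is chosen by extension (``.gtf``/``.gff`` vs ``.bed``) with a
    content sniff as fallback.  Domain intervals are validated against
    transcript length; a domain for an unknown transcript is an error.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gtf", ".gff", ".gff3"):
        models = _load_gtf(path)
    elif suffix == ".bed":
        models = _load_bed12(path)
    else:
        with open(path) as fh:
            first = next((l for l in fh if l.strip() and not l.startswith("#")), "")
        models = (
            _load_gtf(path) if '"' in first and ";" in first else _load_bed12(path)
        )
    ann = GeneAnnotation(models)
    if domain_table is not None:
        domains = load_domain_table(domain_table)
        for tid, (s, e) in domains.items():
            if tid not in ann.transcripts:
                raise AnnotationError(f"domain table references unknown {tid!r}")
            tx = ann.transcripts[tid]
            tx.tk_domain = (s, e)
            tx.__post_init__()  # validates containment
    return ann
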