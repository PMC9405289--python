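"""Screening of chimeric reads against exon-junction criteria.

FFPE RNA-seq libraries produce chimeric reads both from genuine fusion
transcripts and from library-preparation artifacts (reverse-transcriptase
template switching, RNA cross-ligation).  A read supporting a genuine
spliced fusion must satisfy four structural criteria:

  c1  its two segments map to transcripts of two *different* genes;
  c2  each segment maps unambiguously (one gene, aligner multiplicity 1);
  c3  the junction coincides with annotated exon termini — the 5' segment
      ends on an exon 3' (donor) boundary and the 3' segment starts on an
      exon 5' (acceptor) boundary, within a configurable tolerance
      (default 0 nt, i.e. exact);
  c4  both segments align sense to their transcripts, so the fusion is one
      transcriptional unit.

Reads passing all four are grouped per distinct junction into
:class:`FusionCandidate` objects; distinct junctions of the same gene pair
remain separate candidates (breakpoint variants).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .gene_models import GeneAnnotation, GenomicInterval, TranscriptModel

__all__ = [
    "SegmentAlignment",
    "ChimericRead",
    "ScreenResult",
    "FusionCandidate",
    "screen_read",
    "screen_reads",
    "group_candidates",
    "count_unique_reads",
    "read_candidates",
    "write_screen_results",
]

#: minimum nucleotides a moiety must contribute before it can be considered
#: unambiguously assignable (50-nt FFPE reads with shorter overhangs do not
#: anchor a gene reliably)
DEFAULT_MIN_OVERHANG = 10


@dataclass(frozen=True)
class SegmentAlignment:
    """One aligned segment of a chimeric read."""

    query_start: int
    query_end: int
    interval: GenomicInterval
    n_genomic_hits: int = 1

    @property
    def query_length(self) -> int:
        return self.query_end - self.query_start


@dataclass(frozen=True)
class ChimericRead:
    """A read split into a 5' and a 3' segment (in read order)."""

    read_id: str
    sequence: str
    segment5: SegmentAlignment
    segment3: SegmentAlignment
    sample_id: str = ""

    def __post_init__(self) -> None:
        for seg in (self.segment5, self.segment3):
            if seg.query_end > len(self.sequence):
                raise ValueError(
                    f"{self.read_id}: segment query range exceeds read length"
                )
        a, b = self.segment5, self.segment3
        if a.query_end > b.query_start and b.query_end > a.query_start:
            raise ValueError(f"{self.read_id}: segment query ranges overlap")


@dataclass
class ScreenResult:
    """Per-read screening outcome with per-criterion flags."""

    read_id: str
    c1_exon_junction: bool = False
    c2_unambiguous: bool = False
    c3_boundary_match: bool = False
    c4_same_orientation: bool = False
    reason: str = ""
    # (donor transcript_id, donor exon 1-based, acceptor transcript_id,
    #  acceptor exon 1-based) — populated only when all criteria pass
    junction: Optional[tuple[str, int, str, int]] = None

    @property
    def passed(self) -> bool:
        return (
            self.c1_exon_junction
            and self.c2_unambiguous
            and self.c3_boundary_match
            and self.c4_same_orientation
        )


@dataclass
class FusionCandidate:
    """All chimeric-read evidence for one junction in one sample."""

    sample_id: str
    gene5: str
    tx5: str
    exon5: int  # last retained exon of the 5' partner, 1-based
    gene3: str
    tx3: str
    exon3: int  # first retained exon of the 3' partner, 1-based
    reads: list[ChimericRead] = field(default_factory=list)

    @property
    def junction(self) -> tuple[str, int, str, int]:
        return (self.tx5, self.exon5, self.tx3, self.exon3)

    @property
    def n_reads(self) -> int:
        return len(self.reads)


def _segment_hits(
    seg: SegmentAlignment, ann: GeneAnnotation
) -> list[TranscriptModel]:
    iv = seg.interval
    return ann.transcripts_overlapping(iv.chrom, iv.start, iv.end)


def _boundary_match(
    seg: SegmentAlignment, tx: TranscriptModel, side: str, tolerance: int
) -> Optional[int]:
    """Exon index (0-based) whose boundary the segment terminus matches.

    ``side='donor'`` checks the segment's transcript-orientation 3' end
    against exon 3' boundaries; ``side='acceptor'`` checks the segment's 5'
    end against exon 5' boundaries.  Returns None when no exon matches
    within ``tolerance`` nt.
    """
    iv = seg.interval
    # genomic coordinate of the terminus being tested, as an exclusive/
    # inclusive bound depending on strand
    best: Optional[int] = None
    for i, exon in enumerate(tx.exons):
        if side == "donor":
            ref = exon.end if tx.strand == "+" else exon.start
            obs = iv.end if tx.strand == "+" else iv.start
        else:
            ref = exon.start if tx.strand == "+" else exon.end
            obs = iv.start if tx.strand == "+" else iv.end
        if abs(obs - ref) <= tolerance:
            best = i
            break
    return best


def screen_read(
    read: ChimericRead,
    ann: GeneAnnotation,
    tolerance_nt: int = 0,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> ScreenResult:
    """Apply the four junction criteria to one chimeric read.

    Ambiguity (c2) is taken from the upstream aligner's multiplicity field
    together with the annotation: a segment is unambiguous when it overlaps
    exactly one gene and was reported with a single genomic hit.  Boundary
    matching (c3) tries every isoform of the assigned gene and records the
    first (transcript_id-sorted) isoform whose exon boundary matches.
    """
    res = ScreenResult(read_id=read.read_id)
    hits5 = _segment_hits(read.segment5, ann)
    hits3 = _segment_hits(read.segment3, ann)
    if not hits5 or not hits3:
        res.reason = "segment maps to no annotated transcript"
        return res
    genes5 = {t.gene_symbol for t in hits5}
    genes3 = {t.gene_symbol for t in hits3}

    # c1: two different genes
    res.c1_exon_junction = bool(genes5 and genes3) and genes5.isdisjoint(genes3)
    if not res.c1_exon_junction and genes5 & genes3:
        res.reason = "both segments map within one gene"

    # c2: unambiguous mapping
    short = (
        read.segment5.query_length < min_overhang
        or read.segment3.query_length < min_overhang
    )
    res.c2_unambiguous = (
        not short
        and len(genes5) == 1
        and len(genes3) == 1
        and read.segment5.n_genomic_hits == 1
        and read.segment3.n_genomic_hits == 1
    )
    if short and not res.reason:
        res.reason = f"moiety shorter than {min_overhang} nt"

    # c4: sense orientation on both sides
    sense5 = [t for t in hits5 if t.strand == read.segment5.interval.strand]
    sense3 = [t for t in hits3 if t.strand == read.segment3.interval.strand]
    res.c4_same_orientation = bool(sense5) and bool(sense3)

    # c3: exon-boundary match, trying each sense isoform
    donor_hit: Optional[tuple[str, int]] = None
    acceptor_hit: Optional[tuple[str, int]] = None
    for tx in sense5:
        idx = _boundary_match(read.segment5, tx, "donor", tolerance_nt)
        if idx is not None:
            donor_hit = (tx.transcript_id, idx)
            break
    for tx in sense3:
        idx = _boundary_match(read.segment3, tx, "acceptor", tolerance_nt)
        if idx is not None:
            acceptor_hit = (tx.transcript_id, idx)
            break
    res.c3_boundary_match = donor_hit is not None and acceptor_hit is not None
    if res.passed:
        res.junction = (
            donor_hit[0],
            donor_hit[1] + 1,
            acceptor_hit[0],
            acceptor_hit[1] + 1,
        )
    return res


def screen_reads(
    reads: Iterable[ChimericRead],
    ann: GeneAnnotation,
    tolerance_nt: int = 0,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> list[ScreenResult]:
    return [screen_read(r, ann, tolerance_nt, min_overhang) for r in reads]


def group_candidates(
    screened: Sequence[tuple[ChimericRead, ScreenResult]],
    sample_id: str,
    ann: GeneAnnotation,
) -> list[FusionCandidate]:
    """Aggregate passing reads into one candidate per distinct junction.

    Distinct junctions of the same gene pair stay separate (breakpoint
    variants).  Duplicate-sequence reads are retained here; deduplication
    happens in :func:`count_unique_reads`.
    """
    groups: dict[tuple[str, int, str, int], FusionCandidate] = {}
    for read, result in screened:
        if not result.passed or result.junction is None:
            continue
        key = result.junction
        if key not in groups:
            tx5, exon5, tx3, exon3 = key
            groups[key] = FusionCandidate(
                sample_id=sample_id,
                gene5=ann.gene_of(tx5),
                tx5=tx5,
                exon5=exon5,
                gene3=ann.gene_of(tx3),
                tx3=tx3,
                exon3=exon3,
            )
        groups[key].reads.append(read)
    return [groups[k] for k in sorted(groups)]


def count_unique_reads(candidate: FusionCandidate) -> int:
    """Number of supporting reads distinct by sequence.

    Exact sequence duplicates (library PCR duplicates) collapse; reads that
    merely share an alignment start but differ in sequence do not.
    """
    return len({r.sequence for r in candidate.reads})


# -- TSV I/O -------------------------------------------------------------

_SEG_COLS = ("chrom", "start", "end", "strand", "nhits")

#: column aliases accepted by the permissive reader (maps fusion-caller
#: intermediate junction-file headers into the native schema)
_ALIASES = {
    "sample": "sample_id",
    "read_name": "read_id",
    "seq": "sequence",
    "junction_reads_seq": "sequence",
}


def read_candidates(
    path: str | Path, column_map: Optional[dict[str, str]] = None
) -> dict[str, list[ChimericRead]]:
    """Read chimeric-read candidates from TSV, grouped by sample.

    Native schema (one row per read): ``sample_id, read_id, sequence,
    seg5_chrom, seg5_start, seg5_end, seg5_strand, seg5_nhits, seg3_chrom,
    seg3_start, seg3_end, seg3_strand, seg3_nhits``.  Optional
    ``seg5_qstart/seg5_qend`` (and seg3 equivalents) give query ranges;
    otherwise the 5' segment is assumed to cover the read prefix and the 3'
    segment the suffix, split in proportion to the genomic segment lengths.
    ``column_map`` renames non-native headers into this schema on read.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns={c: _ALIASES.get(c.lower(), c) for c in df.columns})
    if column_map:
        df = df.rename(columns=column_map)
    required = ["sample_id", "read_id", "sequence"] + [
        f"seg{n}_{c}" for n in (5, 3) for c in _SEG_COLS
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing candidate columns {missing}")
    out: dict[str, list[ChimericRead]] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        seq = d["sequence"]
        lens = {
            n: int(d[f"seg{n}_end"]) - int(d[f"seg{n}_start"]) for n in (5, 3)
        }
        if "seg5_qstart" in d and pd.notna(d.get("seg5_qstart")):
            q5 = (int(d["seg5_qstart"]), int(d["seg5_qend"]))
            q3 = (int(d["seg3_qstart"]), int(d["seg3_qend"]))
        else:
            split = min(lens[5], len(seq))
            q5, q3 = (0, split), (split, min(split + lens[3], len(seq)))
        segs = {}
        for n, q in ((5, q5), (3, q3)):
            segs[n] = SegmentAlignment(
                query_start=q[0],
                query_end=q[1],
                interval=GenomicInterval(
                    d[f"seg{n}_chrom"],
                    int(d[f"seg{n}_start"]),
                    int(d[f"seg{n}_end"]),
                    d[f"seg{n}_strand"],
                ),
                n_genomic_hits=int(d[f"seg{n}_nhits"]),
            )
        read = ChimericRead(
            read_id=d["read_id"],
            sequence=seq,
            segment5=segs[5],
            segment3=segs[3],
            sample_id=d["sample_id"],
        )
        out.setdefault(d["sample_id"], []).append(read)
    return out


def write_screen_results(
    pairs: Sequence[tuple[ChimericRead, ScreenResult]], path: str | Path
) -> None:
    """Write per-read screening flags and junction fields to TSV."""
    rows = []
    for read, res in pairs:
        j = res.junction or ("", "", "", "")
        rows.append(
            {
                "sample_id": read.sample_id,
                "read_id": read.read_id,
                "c1_exon_junction": res.c1_exon_junction,
                "c2_unambiguous": res.c2_unambiguous,
                "c3_boundary_match": res.c3_boundary_match,
                "c4_same_orientation": res.c4_same_orientation,
                "passed": res.passed,
                "reason": res.reason,
                "tx5": j[0],
                "exon5": j[1],
                "tx3": j[2],
                "exon3": j[3],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
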