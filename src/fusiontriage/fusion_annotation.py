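"""Structural annotation of screened fusion candidates.

Each candidate becomes a :class:`FusionCall` carrying the three structural
features used downstream: which side the receptor tyrosine kinase sits on,
whether the open reading frame is preserved across the junction, and
whether the kinase domain is fully retained in the chimeric transcript.

Breakpoints are transcript coordinates at exon boundaries: the 5' partner
retains ``[0, bp5)`` of its transcript and the 3' partner retains
``[bp3, length)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .candidate_screen import FusionCandidate, count_unique_reads
from .gene_models import GeneAnnotation, TranscriptModel

__all__ = [
    "FusionCall",
    "DomainCoordinatesMissing",
    "annotate_candidate",
    "assign_rtk_side",
    "orf_preserved",
    "tk_retained",
    "write_calls",
    "read_calls",
]

RTK_5P = "5'"
RTK_3P = "3'"
RTK_BOTH = "both"
RTK_NONE = "none"


class DomainCoordinatesMissing(ValueError):
    """The RTK partner has no annotated kinase-domain interval."""


@dataclass
class FusionCall:
    """An annotated fusion: partners, breakpoints and structural features."""

    sample_id: str
    gene5: str
    tx5: str
    bp5: int  # transcript coord; 5' partner retains [0, bp5)
    exon5: int  # last retained exon, 1-based
    gene3: str
    tx3: str
    bp3: int  # transcript coord; 3' partner retains [bp3, length)
    exon3: int  # first retained exon, 1-based
    rtk_side: str = RTK_NONE
    n_unique_reads: int = 0
    orf: Optional[bool] = None
    tk: Optional[bool] = None

    @property
    def name(self) -> str:
        return f"{self.gene5}-{self.gene3}"


def assign_rtk_side(gene5: str, gene3: str, ann: GeneAnnotation) -> str:
    """Which fusion side carries a receptor tyrosine kinase.

    3'-RTK fusions are the clinically typical configuration: a partner
    promoter drives expression of the downstream kinase domain.
    """
    r5, r3 = ann.is_rtk(gene5), ann.is_rtk(gene3)
    if r5 and r3:
        return RTK_BOTH
    if r5:
        return RTK_5P
    if r3:
        return RTK_3P
    return RTK_NONE


def orf_preserved(call: FusionCall, ann: GeneAnnotation) -> bool:
    """Whether the chimeric transcript keeps a single open reading frame.

    True iff both breakpoints fall inside their partners' coding sequences
    and the reading-frame phases at the two breakpoints are equal, so
    translation initiated at the 5' partner's start codon continues the 3'
    partner's protein in its native frame.  A breakpoint in a UTR (such as
    a 3' partner joined within its 5'-untranslated region) or a non-coding
    partner yields False: this is a purely structural phase test, even
    though a native downstream start codon might still produce a protein.
    """
    m5, m3 = ann.get(call.tx5), ann.get(call.tx3)
    if not m5.is_coding or not m3.is_coding:
        return False
    # 5' partner retains [0, bp5): the junction must cut inside its CDS
    if not (m5.cds_start < call.bp5 <= m5.cds_end):
        return False
    # 3' partner retains [bp3, length): first retained base inside its CDS
    if not (m3.cds_start <= call.bp3 < m3.cds_end):
        return False
    return m5.phase_at(call.bp5) == m3.phase_at(call.bp3)


def _rtk_model(call: FusionCall, ann: GeneAnnotation) -> tuple[TranscriptModel, str]:
    """RTK partner model and its side; for two-RTK fusions the 3' partner is
    the evaluated moiety (the downstream-coverage criterion is defined on
    3'-RTK transcripts)."""
    side = call.rtk_side
    if side in (RTK_3P, RTK_BOTH):
        return ann.get(call.tx3), RTK_3P
    if side == RTK_5P:
        return ann.get(call.tx5), RTK_5P
    raise ValueError("tk_retained undefined when neither partner is an RTK")


def tk_retained(call: FusionCall, ann: GeneAnnotation) -> bool:
    """Whether the tyrosine-kinase domain lies fully in the retained moiety.

    Containment is all-or-nothing: a truncated kinase domain is not the
    druggable entity these criteria target, so partial retention is False.
    """
    model, side = _rtk_model(call, ann)
    if model.tk_domain is None:
        raise DomainCoordinatesMissing(
            f"domain coordinates required for {model.transcript_id}"
        )
    s, e = model.tk_domain
    if side == RTK_3P:
        return s >= call.bp3  # domain within [bp3, length)
    return e <= call.bp5  # domain within [0, bp5)


def annotate_candidate(
    candidate: FusionCandidate, ann: GeneAnnotation
) -> FusionCall:
    """Build a fully annotated FusionCall from a screened candidate."""
    m5, m3 = ann.get(candidate.tx5), ann.get(candidate.tx3)
    bp5 = m5.exon_boundaries()[candidate.exon5 - 1]
    bp3 = m3.exon_boundaries()[candidate.exon3 - 2] if candidate.exon3 > 1 else 0
    call = FusionCall(
        sample_id=candidate.sample_id,
        gene5=candidate.gene5,
        tx5=candidate.tx5,
        bp5=bp5,
        exon5=candidate.exon5,
        gene3=candidate.gene3,
        tx3=candidate.tx3,
        bp3=bp3,
        exon3=candidate.exon3,
        n_unique_reads=count_unique_reads(candidate),
    )
    call.rtk_side = assign_rtk_side(call.gene5, call.gene3, ann)
    call.orf = orf_preserved(call, ann)
    call.tk = tk_retained(call, ann) if call.rtk_side != RTK_NONE else False
    return call


def _yn(v: Optional[bool]) -> str:
    return "yes" if v else "no"


def write_calls(calls: Iterable[FusionCall], path: str | Path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "gene5": c.gene5,
            "tx5": c.tx5,
            "exon5": c.exon5,
            "bp5": c.bp5,
            "gene3": c.gene3,
            "tx3": c.tx3,
            "exon3": c.exon3,
            "bp3": c.bp3,
            "rtk_side": c.rtk_side,
            "orf": _yn(c.orf),
            "tk": _yn(c.tk),
            "n_unique_reads": c.n_unique_reads,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[FusionCall]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    calls = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        calls.append(
            FusionCall(
                sample_id=d["sample_id"],
                gene5=d["gene5"],
                tx5=d["tx5"],
                bp5=int(d["bp5"]),
                exon5=int(d["exon5"]),
                gene3=d["gene3"],
                tx3=d["tx3"],
                bp3=int(d["bp3"]),
                exon3=int(d["exon3"]),
                rtk_side=d["rtk_side"],
                n_unique_reads=int(d["n_unique_reads"]),
                orf=d["orf"] == "yes",
                tk=d["tk"] == "yes",
            )
        )
    return calls
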