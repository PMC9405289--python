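"""Synthetic annotations, chimeric reads and coverage profiles.

Everything downstream of a fusion caller can be exercised without any
external data: a toy two-gene annotation (a promoter-donor partner and an
RTK acceptor with a kinase domain), junction-spanning 50-nt single-end
reads placed exactly on — or deliberately offset from — exon boundaries,
and per-exon count profiles where the fusion sample's downstream exons are
scaled by a configurable fold change over lognormal per-exon noise.

The defaults emulate the FFPE study conditions this tool targets: 50-nt
single-end reads, a 20-exon RTK with the junction at exon 12 (the
prototypical RET configuration), ~30 million mapped reads per sample, and
strong (about tenfold) downstream over-expression in fusion-bearing
samples against a 20-sample same-cancer-type control cohort.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .candidate_screen import ChimericRead, SegmentAlignment
from .coverage_stats import NORM_DEPTH, ExonCoverageProfile
from .gene_models import GeneAnnotation, GenomicInterval, TranscriptModel

__all__ = [
    "SimulationConfig",
    "make_toy_annotation",
    "simulate_chimeric_reads",
    "simulate_coverage",
    "write_gtf",
    "write_fasta",
    "write_candidates_tsv",
]


@dataclass
class SimulationConfig:
    """Knobs for the toy-fusion simulators.

    ``junction_exon`` is the 1-based first retained exon of the 3' (RTK)
    partner; ``donor_exon`` the last retained exon of the 5' partner.
    ``fold_change`` scales the downstream-exon count means in the fusion
    sample (1.0 = null); ``noise_cv`` is the per-exon lognormal coefficient
    of variation.  ``boundary_offset_nt`` shifts the simulated junction off
    the exon boundary (0 = clean spliced junction).
    """

    n_exons: int = 20
    exon_length_nt: int = 150
    intron_length_nt: int = 100
    junction_exon: int = 12
    donor_exon: int = 1
    fold_change: float = 10.0
    noise_cv: float = 0.2
    n_controls: int = 20
    n_reads_junction: int = 3
    read_length_nt: int = 50
    boundary_offset_nt: int = 0
    duplicate_rate: float = 0.0
    base_count: int = 200
    depth: int = 30_000_000
    tk_straddles_junction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exons < 2 or self.exon_length_nt < 1:
            raise ValueError("need >=2 exons of positive length")
        if not 1 <= self.junction_exon <= self.n_exons:
            raise ValueError("junction_exon outside 1..n_exons")
        if not 1 <= self.donor_exon <= self.n_exons:
            raise ValueError("donor_exon outside 1..n_exons")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


GENE5 = "PTNR1"  # toy promoter-donor partner
GENE3 = "RET"  # toy RTK acceptor (symbol in the RTK set)
TX5 = "TOY_T5.1"
TX3 = "TOY_T3.1"
_CDS_PAD = 30  # UTR pad; multiple of 3 so exon-boundary phases are 0


def _toy_transcript(
    gene: str, tid: str, chrom: str, cfg: SimulationConfig,
    tk_domain: Optional[tuple[int, int]] = None,
) -> TranscriptModel:
    exons = []
    pos = 100
    for _ in range(cfg.n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + cfg.exon_length_nt, "+"))
        pos += cfg.exon_length_nt + cfg.intron_length_nt
    length = cfg.n_exons * cfg.exon_length_nt
    return TranscriptModel(
        gene_symbol=gene,
        transcript_id=tid,
        exons=exons,
        cds_start=_CDS_PAD,
        cds_end=length - _CDS_PAD,
        tk_domain=tk_domain,
    )


def make_toy_annotation(
    config: SimulationConfig,
) -> tuple[GeneAnnotation, dict[str, str]]:
    """Two toy genes plus random reference sequences, seeded.

    The 3' gene carries an RTK symbol and a kinase domain placed fully
    downstream of the junction exon (so a clean junction retains it), or
    straddling the junction when ``tk_straddles_junction`` is set.
    """
    rng = np.random.default_rng(config.seed)
    L = config.exon_length_nt
    bp3 = (config.junction_exon - 1) * L  # first retained base
    length = config.n_exons * L
    if config.tk_straddles_junction:
        tk = (max(0, bp3 - L), min(length, bp3 + L))
    else:
        tk = (min(bp3 + L, length - L), min(bp3 + 3 * L, length))
    tx5 = _toy_transcript(GENE5, TX5, "chrT5", config)
    tx3 = _toy_transcript(GENE3, TX3, "chrT3", config, tk_domain=tk)
    ann = GeneAnnotation([tx5, tx3])
    refs = {}
    for tx in (tx5, tx3):
        span = max(e.end for e in tx.exons) + 100
        refs[tx.chrom] = "".join(rng.choice(list("ACGT"), size=span))
    return ann, refs


def simulate_chimeric_reads(
    config: SimulationConfig,
    ann: GeneAnnotation,
    refs: dict[str, str],
    sample_id: str = "SIM-1",
) -> list[ChimericRead]:
    """Junction-spanning reads with a controlled boundary offset.

    Each read's 5' segment ends ``boundary_offset_nt`` away from the donor
    exon's 3' boundary and its 3' segment starts the same offset from the
    acceptor exon's 5' boundary; offset 0 gives cleanly spliced junction
    reads that pass boundary matching at tolerance 0.  A ``duplicate_rate``
    fraction of reads reuses the previous read's sequence (PCR-duplicate
    emulation).
    """
    rng = np.random.default_rng(config.seed + 1)
    tx5, tx3 = ann.get(TX5), ann.get(TX3)
    e5 = tx5.exons[config.donor_exon - 1]
    e3 = tx3.exons[config.junction_exon - 1]
    L = config.read_length_nt
    off = config.boundary_offset_nt
    reads: list[ChimericRead] = []
    prev: Optional[ChimericRead] = None
    for i in range(config.n_reads_junction):
        if prev is not None and rng.random() < config.duplicate_rate:
            dup = ChimericRead(
                read_id=f"{sample_id}:read{i}",
                sequence=prev.sequence,
                segment5=prev.segment5,
                segment3=prev.segment3,
                sample_id=sample_id,
            )
            reads.append(dup)
            continue
        s5 = int(rng.integers(15, L - 15 + 1))  # overhang >= 15 nt each side
        s3 = L - s5
        g5_end = e5.end + off
        g3_start = e3.start + off
        seg5 = SegmentAlignment(0, s5, GenomicInterval("chrT5", g5_end - s5, g5_end, "+"))
        seg3 = SegmentAlignment(s5, L, GenomicInterval("chrT3", g3_start, g3_start + s3, "+"))
        seq = refs["chrT5"][g5_end - s5 : g5_end] + refs["chrT3"][g3_start : g3_start + s3]
        read = ChimericRead(
            read_id=f"{sample_id}:read{i}",
            sequence=seq,
            segment5=seg5,
            segment3=seg3,
            sample_id=sample_id,
        )
        reads.append(read)
        prev = read
    return reads


def _noisy_counts(
    means: np.ndarray, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Lognormal, mean-preserving integer counts at the given CV."""
    if cv <= 0:
        return np.rint(means).astype(int)
    sigma = np.sqrt(np.log1p(cv * cv))
    factors = rng.lognormal(mean=-sigma * sigma / 2, sigma=sigma, size=means.shape)
    return np.rint(means * factors).astype(int)


def simulate_coverage(
    config: SimulationConfig, norm_mode: str = NORM_DEPTH
) -> tuple[ExonCoverageProfile, list[ExonCoverageProfile]]:
    """A fusion-sample coverage profile plus control-cohort profiles.

    Controls draw i.i.d. per-exon counts around ``base_count``; the fusion
    sample multiplies the means of exons from ``junction_exon`` onward by
    ``fold_change``.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_exons
    lengths = np.full(n, config.exon_length_nt)
    base = np.full(n, float(config.base_count))
    fused = base.copy()
    fused[config.junction_exon - 1 :] *= config.fold_change
    fusion = ExonCoverageProfile(
        sample_id="SIM-1",  # same sample as the simulated junction reads
        transcript_id=TX3,
        counts=_noisy_counts(fused, config.noise_cv, rng),
        lengths=lengths,
        depth=config.depth,
        norm_mode=norm_mode,
    )
    controls = [
        ExonCoverageProfile(
            sample_id=f"CTRL-{j + 1}",
            transcript_id=TX3,
            counts=_noisy_counts(base, config.noise_cv, rng),
            lengths=lengths,
            depth=config.depth,
            norm_mode=norm_mode,
        )
        for j in range(config.n_controls)
    ]
    return fusion, controls


# -- serialization -------------------------------------------------------

def write_gtf(ann: GeneAnnotation, path: str | Path) -> None:
    """Write the annotation as Ensembl-dialect GTF (exon + CDS features)."""
    lines = []
    for tx in ann:
        attrs = (
            f'gene_id "{tx.gene_symbol}"; transcript_id "{tx.transcript_id}"; '
            f'gene_name "{tx.gene_symbol}";'
        )
        for exon in tx.exons:
            lines.append(
                "\t".join(
                    [
                        exon.chrom, "toy", "exon",
                        str(exon.start + 1), str(exon.end),
                        ".", exon.strand, ".", attrs,
                    ]
                )
            )
        if tx.is_coding:
            offset = 0
            for exon in tx.exons:
                lo = max(tx.cds_start, offset)
                hi = min(tx.cds_end, offset + len(exon))
                if lo < hi:
                    if tx.strand == "+":
                        g0 = exon.start + (lo - offset)
                        g1 = exon.start + (hi - offset)
                    else:
                        g0 = exon.end - (hi - offset)
                        g1 = exon.end - (lo - offset)
                    lines.append(
                        "\t".join(
                            [
                                exon.chrom, "toy", "CDS",
                                str(g0 + 1), str(g1),
                                ".", exon.strand, ".", attrs,
                            ]
                        )
                    )
                offset += len(exon)
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(refs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in refs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_candidates_tsv(reads: list[ChimericRead], path: str | Path) -> None:
    """Write reads in the native candidate TSV schema."""
    header = [
        "sample_id", "read_id", "sequence",
        "seg5_chrom", "seg5_start", "seg5_end", "seg5_strand", "seg5_nhits",
        "seg5_qstart", "seg5_qend",
        "seg3_chrom", "seg3_start", "seg3_end", "seg3_strand", "seg3_nhits",
        "seg3_qstart", "seg3_qend",
    ]
    rows = ["\t".join(header)]
    for r in reads:
        rows.append(
            "\t".join(
                str(x)
                for x in [
                    r.sample_id, r.read_id, r.sequence,
                    r.segment5.interval.chrom, r.segment5.interval.start,
                    r.segment5.interval.end, r.segment5.interval.strand,
                    r.segment5.n_genomic_hits, r.segment5.query_start,
                    r.segment5.query_end,
                    r.segment3.interval.chrom, r.segment3.interval.start,
                    r.segment3.interval.end, r.segment3.interval.strand,
                    r.segment3.n_genomic_hits, r.segment3.query_start,
                    r.segment3.query_end,
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")
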