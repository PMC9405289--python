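"""Exon-coverage statistics for the downstream-coverage fusion criterion.

A genuine 3'-RTK fusion places the kinase-encoding exons under the 5'
partner's promoter, so in the fusion-bearing sample the RTK exons
*downstream* of the junction are covered by more reads than the upstream
exons that are not part of the chimera.  Two complementary tests detect
this asymmetry:

* a within-sample one-sided Welch t-test on length-normalized per-exon
  coverage, downstream > upstream;
* a cross-sample pattern against a control-cohort baseline: every
  downstream exon above the controls' 95th percentile while every upstream
  exon stays within the 95% confidence interval of the control mean.

Per-exon read counts are double-normalized: by exon length, and by a
per-sample factor — total mapped reads ("depth" mode, reads per kilobase
per million, used within one sample where the constant cancels in the
t-test) or the gene's own total counts ("gene" mode, used for cross-sample
cohort comparison, where it removes between-sample expression differences).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .fusion_annotation import RTK_3P, RTK_5P, RTK_BOTH, RTK_NONE, FusionCall
from .gene_models import TranscriptModel

__all__ = [
    "ExonCoverageProfile",
    "CohortBaseline",
    "AsymmetryResult",
    "exon_counts",
    "normalize",
    "split_at_junction",
    "asymmetry_ttest",
    "cohort_pattern",
    "downstream_criterion",
    "moiety_expression",
    "read_counts_table",
    "write_counts_table",
    "read_sample_manifest",
]

NORM_DEPTH = "depth"
NORM_GENE = "gene"

MET_YES = "yes"
MET_NO = "no"
MET_ND = "ND"  # not determined: criterion defined only for 3'-RTK fusions


def normalize(
    counts: Sequence[float],
    lengths: Sequence[float],
    depth: Optional[float] = None,
    norm_mode: str = NORM_DEPTH,
) -> np.ndarray:
    """Double-normalize per-exon read counts.

    depth mode
        ``counts / (length/1e3) / (depth/1e6)`` — reads per kilobase of
        exon per million mapped reads.
    gene mode
        ``counts / length / sum(counts)`` — per-kilobase share of the
        gene's own reads; an unexpressed gene (all-zero counts) maps to all
        zeros rather than dividing by zero.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths differ in shape")
    if np.any(lengths <= 0):
        raise ValueError("exon lengths must be positive")
    if norm_mode == NORM_DEPTH:
        if depth is None or depth <= 0:
            raise ValueError("depth mode requires a positive total-read depth")
        return counts / (lengths / 1e3) / (depth / 1e6)
    if norm_mode == NORM_GENE:
        total = counts.sum()
        if total == 0:
            return np.zeros_like(counts)
        return counts / lengths / total
    raise ValueError(f"unknown norm_mode {norm_mode!r}")


@dataclass
class ExonCoverageProfile:
    """Per-exon coverage of one transcript in one sample."""

    sample_id: str
    transcript_id: str
    counts: np.ndarray
    lengths: np.ndarray
    depth: Optional[int] = None
    norm_mode: str = NORM_DEPTH
    values: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.counts.shape != self.lengths.shape:
            raise ValueError("counts and lengths differ in length")
        self.values = normalize(self.counts, self.lengths, self.depth, self.norm_mode)

    @property
    def n_exons(self) -> int:
        return len(self.counts)

    def with_mode(self, norm_mode: str) -> "ExonCoverageProfile":
        """Same raw counts re-normalized under another mode."""
        return ExonCoverageProfile(
            self.sample_id, self.transcript_id, self.counts, self.lengths,
            self.depth, norm_mode,
        )


def exon_counts(alignment_source: str | Path, model: TranscriptModel) -> np.ndarray:
    """Count reads overlapping each exon by >=1 base (multicov-equivalent).

    A junction-spanning read overlapping two exons increments both.  BAM
    input must be coordinate-sorted and indexed; uncompressed SAM is
    streamed and counted in memory.  Counts are in genomic order mapped
    back to transcript (5'->3') exon order.
    """
    path = Path(alignment_source)
    counts = np.zeros(model.n_exons, dtype=int)
    if path.suffix == ".sam":
        with pysam.AlignmentFile(str(path), "r") as af:
            if model.chrom not in af.references:
                raise ValueError(f"chromosome {model.chrom!r} absent from alignment header")
            for read in af:
                if read.is_unmapped or read.reference_name != model.chrom:
                    continue
                rs, re_ = read.reference_start, read.reference_end
                for i, exon in enumerate(model.exons):
                    if exon.overlaps(rs, re_):
                        counts[i] += 1
    else:
        with pysam.AlignmentFile(str(path), "rb") as af:
            if model.chrom not in af.references:
                raise ValueError(f"chromosome {model.chrom!r} absent from alignment header")
            for i, exon in enumerate(model.exons):
                counts[i] = af.count(model.chrom, exon.start, exon.end)
    return counts


@dataclass
class CohortBaseline:
    """Per-exon control-cohort statistics for one transcript.

    For every exon across ``n`` control samples: mean, standard deviation,
    empirical 95th percentile (linear interpolation), and the t-based 95%
    confidence interval of the mean.
    """

    transcript_id: str
    n: int
    mean: np.ndarray
    sd: np.ndarray
    p95: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    norm_mode: str = NORM_GENE

    @classmethod
    def from_profiles(
        cls, profiles: Sequence[ExonCoverageProfile]
    ) -> "CohortBaseline":
        if len(profiles) < 2:
            raise ValueError("cohort baseline needs >=2 control samples")
        tids = {p.transcript_id for p in profiles}
        modes = {p.norm_mode for p in profiles}
        if len(tids) != 1 or len(modes) != 1:
            raise ValueError("control profiles mix transcripts or norm modes")
        mat = np.vstack([p.values for p in profiles])  # samples x exons
        n = mat.shape[0]
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1)
        sem = sd / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
        return cls(
            transcript_id=tids.pop(),
            n=n,
            mean=mean,
            sd=sd,
            p95=np.quantile(mat, 0.95, axis=0),
            ci_low=mean - tcrit * sem,
            ci_high=mean + tcrit * sem,
            norm_mode=modes.pop(),
        )


@dataclass
class AsymmetryResult:
    """Outcome of the within-sample downstream-vs-upstream coverage test."""

    t_statistic: float
    p_value: float
    direction: str  # downstream_greater | upstream_greater | none
    n_up: int
    n_down: int
    criterion_met: str  # yes | no | ND
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "t_statistic": None if np.isnan(self.t_statistic) else float(self.t_statistic),
            "p_value": None if np.isnan(self.p_value) else float(self.p_value),
            "direction": self.direction,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "criterion_met": self.criterion_met,
            "reason": self.reason,
        }


def split_at_junction(
    values: Sequence[float], first_retained_exon_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split per-exon values around the junction of the 3' partner.

    ``first_retained_exon_index`` is 1-based exon ``k``: exons ``1..k-1``
    are upstream (absent from the fusion transcript), ``k..last`` are the
    retained downstream exons.  ``k = 1`` leaves no upstream exons; the
    asymmetry test then reports ND.
    """
    values = np.asarray(values, dtype=float)
    k = first_retained_exon_index
    if not 1 <= k <= len(values):
        raise ValueError(f"junction exon {k} outside 1..{len(values)}")
    return values[: k - 1], values[k - 1 :]


def asymmetry_ttest(
    upstream: Sequence[float],
    downstream: Sequence[float],
    alpha: float = 0.05,
    equal_var: bool = False,
    alternative: str = "greater",
) -> AsymmetryResult:
    """One-sided Welch t-test for downstream coverage exceeding upstream.

    Exons are treated as independent observations.  The default is the
    unequal-variance (Welch) test with alternative downstream > upstream;
    ``equal_var=True`` or ``alternative='two-sided'`` select the pooled or
    two-sided variants.  Fewer than two exons on either side cannot give a
    finite t: the criterion is then "no" with a reason (the cohort pattern
    may still fire for such fusions).
    """
    up = np.asarray(upstream, dtype=float)
    down = np.asarray(downstream, dtype=float)
    if len(up) == 0:
        return AsymmetryResult(
            np.nan, np.nan, "none", 0, len(down), MET_ND, "no upstream exons"
        )
    if len(up) < 2 or len(down) < 2:
        return AsymmetryResult(
            np.nan, np.nan, "none", len(up), len(down), MET_NO,
            "insufficient exons",
        )
    res = stats.ttest_ind(down, up, equal_var=equal_var, alternative=alternative)
    t, p = float(res.statistic), float(res.pvalue)
    if down.mean() > up.mean():
        direction = "downstream_greater"
    elif down.mean() < up.mean():
        direction = "upstream_greater"
    else:
        direction = "none"
    if np.isnan(p):  # both sides constant: no evidence either way
        met, reason = MET_NO, "zero variance on both sides"
    elif alternative == "greater":
        met, reason = (MET_YES if p < alpha else MET_NO), ""
    else:
        # a two-sided p must be paired with the direction check
        met = MET_YES if (p < alpha and direction == "downstream_greater") else MET_NO
        reason = ""
    return AsymmetryResult(t, p, direction, len(up), len(down), met, reason)


def cohort_pattern(
    profile: ExonCoverageProfile,
    baseline: CohortBaseline,
    first_retained_exon_index: int,
    fraction: float = 1.0,
) -> bool:
    """Cross-sample coverage pattern against the control cohort.

    True when the fusion sample's downstream exons all exceed the
    controls' per-exon 95th percentile while the upstream exons all fall
    within the 95% confidence interval of the control mean.  ``fraction``
    relaxes "all" to "at least this fraction of exons" on each side
    (default 1.0, strict).
    """
    if profile.transcript_id != baseline.transcript_id:
        raise ValueError(
            f"profile transcript {profile.transcript_id!r} does not match "
            f"baseline {baseline.transcript_id!r}"
        )
    if profile.norm_mode != baseline.norm_mode:
        raise ValueError("profile and baseline use different norm modes")
    k = first_retained_exon_index
    up, down = split_at_junction(profile.values, k)
    up_lo, _ = split_at_junction(baseline.ci_low, k)
    up_hi, _ = split_at_junction(baseline.ci_high, k)
    _, down_p95 = split_at_junction(baseline.p95, k)
    if len(down) == 0:
        return False
    down_ok = np.mean(down > down_p95) >= fraction
    if len(up) == 0:
        up_ok = True  # vacuous: whole gene retained
    else:
        up_ok = np.mean((up >= up_lo) & (up <= up_hi)) >= fraction
    return bool(down_ok and up_ok)


def downstream_criterion(
    asym: Optional[AsymmetryResult],
    cohort: Optional[bool],
    rtk_side: str,
) -> str:
    """Combine the two downstream-coverage tests into one criterion.

    Defined only for fusions whose RTK moiety is downstream (3' side;
    two-RTK fusions are evaluated on their 3' partner): 5'-RTK and
    non-RTK fusions return ND.  Otherwise "yes" when either the
    within-sample t-test or the cohort pattern fires (and/or semantics).
    """
    if rtk_side not in (RTK_3P, RTK_BOTH):
        return MET_ND
    t_yes = asym is not None and asym.criterion_met == MET_YES
    c_yes = bool(cohort)
    return MET_YES if (t_yes or c_yes) else MET_NO


def moiety_expression(
    call: FusionCall,
    profile5: ExonCoverageProfile,
    profile3: ExonCoverageProfile,
) -> tuple[float, float]:
    """Mean normalized coverage of each partner's retained exons.

    Reported per fusion for concordance inspection only; it does not feed
    the classifier.  Profiles must be depth-normalized.  Zero retained
    exons on a side yields NaN for that side.
    """
    for p in (profile5, profile3):
        if p.norm_mode != NORM_DEPTH:
            raise ValueError("moiety expression expects depth-normalized profiles")
    retained5 = profile5.values[: call.exon5]
    retained3 = profile3.values[call.exon3 - 1 :]
    mean5 = float(np.mean(retained5)) if len(retained5) else float("nan")
    mean3 = float(np.mean(retained3)) if len(retained3) else float("nan")
    return mean5, mean3


# -- tabular I/O ---------------------------------------------------------

def write_counts_table(
    rows: Iterable[tuple[str, str, int, int]], path: str | Path
) -> None:
    """Write per-exon counts: sample_id, transcript_id, exon_index (1-based),
    count."""
    df = pd.DataFrame(
        rows, columns=["sample_id", "transcript_id", "exon_index", "count"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_counts_table(path: str | Path) -> dict[tuple[str, str], np.ndarray]:
    """Read a counts TSV into {(sample_id, transcript_id): counts array}."""
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, str], np.ndarray] = {}
    for (sid, tid), grp in df.groupby(["sample_id", "transcript_id"]):
        grp = grp.sort_values("exon_index")
        idx = grp["exon_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise ValueError(
                f"{path}: non-contiguous exon indices for {sid}/{tid}"
            )
        out[(str(sid), str(tid))] = grp["count"].to_numpy()
    return out


def read_sample_manifest(path: str | Path) -> dict[str, int]:
    """Read sample depths: TSV with columns sample_id, depth."""
    df = pd.read_csv(path, sep="\t")
    return {str(r.sample_id): int(r.depth) for r in df.itertuples(index=False)}
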