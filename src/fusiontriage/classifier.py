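"""Rule-based fusion verdicts and sensitivity/specificity evaluation.

Five binary criteria summarize the evidence for each putative fusion:

  orf         open reading frame preserved across the junction
  tk          tyrosine-kinase domain fully retained
  in_db       the ordered gene pair occurs in public fusion catalogs
  downstream  coverage of the RTK exons downstream of the junction is
              elevated (t-test and/or cohort pattern; ND for fusions whose
              RTK is not the 3' partner)
  multiread   supported by more than one non-duplicated chimeric read

A fusion is called positive when at least ``k`` criteria are met (default
thresholds of interest: 2 and 3).  For the clinically relevant subgroup of
in-frame, domain-retaining fusions, a secondary rule requires >=2 of the
remaining three criteria.  Evaluation against confirmed / non-confirmed
labels yields per-criterion and per-threshold sensitivity and specificity;
rows whose downstream criterion is ND are excluded from that criterion's
denominators but retained (as not-met) in threshold scoring.

The packaged feature matrix ``data/rtk_fusion_features.tsv`` transcribes a
published 36-fusion FFPE cohort (10 RT-PCR-confirmed, 15 non-confirmed, 11
experimentally unexplored) with all criterion columns, and serves as the
reference evaluation set.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .coverage_stats import MET_ND, MET_NO, MET_YES

__all__ = [
    "CriterionVector",
    "FusionCatalog",
    "EvaluationReport",
    "db_lookup",
    "score",
    "classify",
    "classify_subgroup",
    "evaluate",
    "load_feature_matrix",
    "feature_matrix_vectors",
    "load_catalog",
    "packaged_feature_matrix_path",
    "packaged_catalog_path",
]

LABEL_CONFIRMED = "confirmed"
LABEL_NON_CONFIRMED = "non_confirmed"
LABEL_UNEXPLORED = "unexplored"

CRITERIA = ("orf", "tk", "in_db", "downstream", "multiread")

POSITIVE = "positive"
NEGATIVE = "negative"
NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class CriterionVector:
    """The five criteria for one putative fusion.

    ``downstream`` is tri-state ("yes"/"no"/"ND"); the other four are
    booleans.  ``multiread`` means more than one unique supporting read.
    """

    orf: bool
    tk: bool
    in_db: bool
    downstream: str
    multiread: bool

    def __post_init__(self) -> None:
        if self.downstream not in (MET_YES, MET_NO, MET_ND):
            raise ValueError(f"downstream must be yes/no/ND, got {self.downstream!r}")

    def met(self, criterion: str) -> bool:
        """Is the named criterion met?  ND counts as not met."""
        v = getattr(self, criterion)
        return v == MET_YES if criterion == "downstream" else bool(v)


def score(vector: CriterionVector) -> int:
    """Number of met criteria, 0..5 (ND counts as not met)."""
    return sum(vector.met(c) for c in CRITERIA)


def classify(vector: CriterionVector, k: int) -> str:
    """Positive iff at least ``k`` of the five criteria are met."""
    if not 1 <= k <= 5:
        raise ValueError(f"threshold k must be in 1..5, got {k}")
    return POSITIVE if score(vector) >= k else NEGATIVE


def classify_subgroup(vector: CriterionVector) -> str:
    """Secondary rule for in-frame fusions with an intact kinase domain.

    Only such fusions encode a potentially druggable chimeric kinase; for
    them, a positive verdict requires at least two of {in_db, downstream,
    multiread}.  Returns "not_applicable" otherwise.
    """
    if not (vector.orf and vector.tk):
        return NOT_APPLICABLE
    n = sum(vector.met(c) for c in ("in_db", "downstream", "multiread"))
    return POSITIVE if n >= 2 else NEGATIVE


class FusionCatalog:
    """Known-fusion catalog: a set of ordered (5', 3') gene-symbol pairs."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs = {(a.upper(), b.upper()) for a, b in pairs}

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return (a.upper(), b.upper()) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FusionCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"gene5", "gene3"} <= set(df.columns):
            raise ValueError(f"{path}: catalog needs gene5 and gene3 columns")
        return cls(zip(df["gene5"], df["gene3"]))


def db_lookup(pair: tuple[str, str], catalog: FusionCatalog) -> bool:
    """Ordered membership of a (5' gene, 3' gene) pair in the catalog.

    Order matters: the catalogs index directional fusions, so (BCR, ABL1)
    present does not imply (ABL1, BCR).
    """
    return pair in catalog


# -- evaluation ----------------------------------------------------------

def _sn_sp(
    records: Sequence[tuple[CriterionVector, str]], criterion: str
) -> dict:
    """Per-criterion Sn/Sp with ND rows excluded from both denominators."""
    def assessable(v: CriterionVector) -> bool:
        return not (criterion == "downstream" and v.downstream == MET_ND)

    conf = [v for v, l in records if l == LABEL_CONFIRMED and assessable(v)]
    nonc = [v for v, l in records if l == LABEL_NON_CONFIRMED and assessable(v)]
    tp = sum(v.met(criterion) for v in conf)
    tn = sum(not v.met(criterion) for v in nonc)
    return {
        "sn": tp / len(conf) if conf else float("nan"),
        "sp": tn / len(nonc) if nonc else float("nan"),
        "sn_fraction": [tp, len(conf)],
        "sp_fraction": [tn, len(nonc)],
    }


@dataclass
class EvaluationReport:
    """Per-criterion and per-threshold Sn/Sp over a labeled fusion set."""

    n_confirmed: int
    n_non_confirmed: int
    n_unexplored: int
    per_criterion: dict[str, dict]
    per_threshold: dict[int, dict]
    fraction_all_five: float
    subgroup: dict

    def rounded(self, ndigits: int = 2) -> dict:
        """Sn/Sp rounded to the reporting precision (2 decimals)."""
        out = {
            c: {"sn": round(d["sn"], ndigits), "sp": round(d["sp"], ndigits)}
            for c, d in self.per_criterion.items()
        }
        thr = {
            k: {"sn": round(d["sn"], ndigits), "sp": round(d["sp"], ndigits)}
            for k, d in self.per_threshold.items()
        }
        return {"per_criterion": out, "per_threshold": thr}

    def to_dict(self) -> dict:
        return {
            "n_confirmed": self.n_confirmed,
            "n_non_confirmed": self.n_non_confirmed,
            "n_unexplored": self.n_unexplored,
            "per_criterion": self.per_criterion,
            "per_threshold": {str(k): v for k, v in self.per_threshold.items()},
            "fraction_all_five": self.fraction_all_five,
            "subgroup": self.subgroup,
        }

    def to_text(self) -> str:
        lines = [
            f"confirmed={self.n_confirmed} non_confirmed={self.n_non_confirmed} "
            f"unexplored={self.n_unexplored}",
            "per-criterion Sn/Sp:",
        ]
        for c, d in self.per_criterion.items():
            lines.append(
                f"  {c:<11} Sn {d['sn']:.2f} ({d['sn_fraction'][0]}/{d['sn_fraction'][1]})"
                f"  Sp {d['sp']:.2f} ({d['sp_fraction'][0]}/{d['sp_fraction'][1]})"
            )
        lines.append("per-threshold (>=k of 5):")
        for k, d in self.per_threshold.items():
            lines.append(f"  k={k}  Sn {d['sn']:.2f}  Sp {d['sp']:.2f}")
        lines.append(
            f"confirmed fusions meeting all five criteria: "
            f"{self.fraction_all_five:.0%}"
        )
        sg = self.subgroup
        lines.append(
            "in-frame+TK subgroup (>=2 of in_db/downstream/multiread): "
            f"Sn {sg['threshold_sn']:.2f}, Sp {sg['threshold_sp']:.2f} "
            f"(literature-inclusive Sn {sg['threshold_sn_literature']:.2f})"
        )
        return "\n".join(lines)


def evaluate(
    records: Sequence[tuple[CriterionVector, str]],
    literature_db: Optional[Sequence[bool]] = None,
) -> EvaluationReport:
    """Evaluate the criteria and thresholds against validation labels.

    ``records`` pairs each CriterionVector with a label (confirmed /
    non_confirmed / unexplored); unexplored rows are excluded from all
    Sn/Sp.  ``literature_db`` optionally flags fusions absent from the
    catalogs but reported in the literature; the subgroup threshold Sn is
    additionally reported under the convention that counts those as
    database-positive.
    """
    labels = {l for _, l in records}
    if LABEL_CONFIRMED not in labels or LABEL_NON_CONFIRMED not in labels:
        raise ValueError("evaluation needs >=1 confirmed and >=1 non-confirmed label")
    if literature_db is None:
        literature_db = [False] * len(records)
    if len(literature_db) != len(records):
        raise ValueError("literature_db length mismatch")

    labeled = [
        (v, l) for (v, l) in records if l in (LABEL_CONFIRMED, LABEL_NON_CONFIRMED)
    ]
    conf = [v for v, l in labeled if l == LABEL_CONFIRMED]
    nonc = [v for v, l in labeled if l == LABEL_NON_CONFIRMED]

    per_criterion = {c: _sn_sp(labeled, c) for c in CRITERIA}

    per_threshold = {}
    for k in range(1, 6):
        tp = sum(classify(v, k) == POSITIVE for v in conf)
        tn = sum(classify(v, k) == NEGATIVE for v in nonc)
        per_threshold[k] = {
            "sn": tp / len(conf),
            "sp": tn / len(nonc),
            "sn_fraction": [tp, len(conf)],
            "sp_fraction": [tn, len(nonc)],
        }

    fraction_all_five = sum(score(v) == 5 for v in conf) / len(conf)

    # subgroup: in-frame + TK-retained fusions, criteria (in_db, downstream,
    # multiread), threshold >=2 of 3
    sub_conf = [v for v in conf if v.orf and v.tk]
    sub_nonc = [v for v in nonc if v.orf and v.tk]
    sub_criteria = {}
    for c in ("in_db", "downstream", "multiread"):
        assessable = [
            v for v in sub_conf
            if not (c == "downstream" and v.downstream == MET_ND)
        ]
        num = sum(v.met(c) for v in assessable)
        sub_criteria[c] = {
            "sn": num / len(assessable) if assessable else float("nan"),
            "sn_fraction": [num, len(assessable)],
        }
    sub_tp = sum(classify_subgroup(v) == POSITIVE for v in sub_conf)
    sub_tn = sum(classify_subgroup(v) == NEGATIVE for v in sub_nonc)

    # literature-inclusive convention: a fusion reported in the literature
    # but absent from the catalogs counts as database-positive
    lit_vectors = []
    for (v, l), lit in zip(records, literature_db):
        if l == LABEL_CONFIRMED:
            lit_vectors.append(
                CriterionVector(v.orf, v.tk, v.in_db or lit, v.downstream, v.multiread)
            )
    lit_conf = [v for v in lit_vectors if v.orf and v.tk]
    sub_tp_lit = sum(classify_subgroup(v) == POSITIVE for v in lit_conf)

    subgroup = {
        "n_confirmed": len(sub_conf),
        "n_non_confirmed": len(sub_nonc),
        "per_criterion": sub_criteria,
        "threshold_sn": sub_tp / len(sub_conf) if sub_conf else float("nan"),
        "threshold_sp": sub_tn / len(sub_nonc) if sub_nonc else float("nan"),
        "threshold_sn_literature": (
            sub_tp_lit / len(lit_conf) if lit_conf else float("nan")
        ),
    }

    return EvaluationReport(
        n_confirmed=len(conf),
        n_non_confirmed=len(nonc),
        n_unexplored=sum(l == LABEL_UNEXPLORED for _, l in records),
        per_criterion=per_criterion,
        per_threshold=per_threshold,
        fraction_all_five=fraction_all_five,
        subgroup=subgroup,
    )


# -- packaged fixtures ---------------------------------------------------

def packaged_feature_matrix_path() -> Path:
    return Path(
        importlib.resources.files("fusiontriage.data") / "rtk_fusion_features.tsv"
    )


def packaged_catalog_path() -> Path:
    return Path(
        importlib.resources.files("fusiontriage.data") / "known_fusion_pairs.tsv"
    )


def load_feature_matrix(path: str | Path | None = None) -> pd.DataFrame:
    """Load the labeled feature matrix (packaged 36-fusion set by default)."""
    if path is None:
        path = packaged_feature_matrix_path()
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "sample_id", "fusion", "orf", "tk", "rtk_side", "in_db",
        "db_literature", "downstream", "n_reads", "label",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["n_reads"] = df["n_reads"].astype(int)
    return df


def feature_matrix_vectors(
    df: pd.DataFrame,
) -> tuple[list[tuple[CriterionVector, str]], list[bool]]:
    """Turn feature-matrix rows into (vector, label) records.

    ``multiread`` derives from the read count (>1 unique reads).  Returns
    the records plus the literature-report flags for the database column.
    """
    records, lit = [], []
    for row in df.itertuples(index=False):
        vec = CriterionVector(
            orf=row.orf == "yes",
            tk=row.tk == "yes",
            in_db=row.in_db == "yes",
            downstream=row.downstream,
            multiread=row.n_reads > 1,
        )
        records.append((vec, row.label))
        lit.append(row.db_literature == "yes")
    return records, lit


def load_catalog(path: str | Path | None = None) -> FusionCatalog:
    if path is None:
        path = packaged_catalog_path()
    return FusionCatalog.from_tsv(path)
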