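"""Docking-score triage: median separation, MCC threshold search, shortlist.

Docking scores are dimensionless with more negative meaning better. A
compound is predicted to be an agonist when its score falls at or below a
threshold t; the threshold is chosen to maximise the Matthews correlation
coefficient (MCC) over known agonists (positives) and antagonists
(negatives). Shortlisting of untested candidates then uses a strict
"score < threshold" rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import mann_whitney_p

CLASS_LABELS = ("agonist", "antagonist", "inactive", "candidate")


@dataclass
class ScoreSet:
    """A class-labelled collection of (compound_id, docking score)."""

    class_label: str
    entries: list[tuple[str, float]]

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        ids = [cid for cid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("compound_ids must be unique within a ScoreSet")
        if not all(math.isfinite(s) for _, s in self.entries):
            raise ValueError("scores must be finite")

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=float)

    @property
    def compound_ids(self) -> list[str]:
        return [cid for cid, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class MedianSeparation:
    median_pos: float
    median_neg: float
    mw_p: float


@dataclass
class ThresholdScan:
    candidate_thresholds: np.ndarray  # sorted ascending
    mcc_values: np.ndarray
    best_threshold: float
    best_mcc: float


@dataclass
class EnrichmentResult:
    top_fraction: float
    ef: float
    n_top: int
    actives_in_top: int


def read_score_csv(path) -> dict[str, ScoreSet]:
    """Load a (compound_id, class, score) CSV into per-class ScoreSets."""
    df = pd.read_csv(path)
    required = {"compound_id", "class", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out = {}
    for label, grp in df.groupby("class", sort=False):
        out[str(label)] = ScoreSet(
            str(label), list(zip(grp["compound_id"].astype(str), grp["score"].astype(float)))
        )
    return out


def median_separation(positives: ScoreSet, negatives: ScoreSet) -> MedianSeparation:
    """Class medians plus a two-sided Mann-Whitney p-value."""
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("both score sets must be non-empty")
    return MedianSeparation(
        median_pos=float(np.median(positives.scores)),
        median_neg=float(np.median(negatives.scores)),
        mw_p=mann_whitney_p(positives.scores, negatives.scores),
    )


def confusion_at_threshold(agonists: ScoreSet, antagonists: ScoreSet, t: float) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) under the rule: predict agonist iff score <= t."""
    tp = int(np.sum(agonists.scores <= t))
    fn = len(agonists) - tp
    fp = int(np.sum(antagonists.scores <= t))
    tn = len(antagonists) - fp
    return tp, fp, fn, tn


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mcc_at_threshold(agonists: ScoreSet, antagonists: ScoreSet, t: float) -> float:
    if len(agonists) == 0 or len(antagonists) == 0:
        raise ValueError("both score sets must be non-empty")
    return mcc(*confusion_at_threshold(agonists, antagonists, t))


def scan_threshold(agonists: ScoreSet, antagonists: ScoreSet) -> ThresholdScan:
    """Exhaustive MCC scan over every observed score.

    With the "score <= t" prediction rule the MCC is a step function that
    only changes at observed scores, so scanning the pooled score multiset
    attains the global optimum. Ties on MCC break toward the most negative
    (most stringent) threshold.
    """
    if len(agonists) == 0 or len(antagonists) == 0:
        raise ValueError("both score sets must be non-empty")
    thresholds = np.sort(np.concatenate([agonists.scores, antagonists.scores]))
    mccs = np.array([mcc_at_threshold(agonists, antagonists, t) for t in thresholds])
    best_idx = int(np.argmax(mccs))  # argmax takes the first (most negative) maximiser
    return ThresholdScan(
        candidate_thresholds=thresholds,
        mcc_values=mccs,
        best_threshold=float(thresholds[best_idx]),
        best_mcc=float(mccs[best_idx]),
    )


def scan_table(agonists: ScoreSet, antagonists: ScoreSet) -> pd.DataFrame:
    rows = []
    for t in np.sort(np.concatenate([agonists.scores, antagonists.scores])):
        tp, fp, fn, tn = confusion_at_threshold(agonists, antagonists, t)
        rows.append({"threshold": t, "tp": tp, "fp": fp, "fn": fn, "tn": tn, "mcc": mcc(tp, fp, fn, tn)})
    return pd.DataFrame(rows)


def shortlist(candidates: ScoreSet, threshold: float) -> list[str]:
    """Compound ids scoring strictly below the threshold, input order kept."""
    return [cid for cid, s in candidates.entries if s < threshold]


def enrichment_factor(actives: ScoreSet, decoys: ScoreSet, top_fraction: float) -> EnrichmentResult:
    """Enrichment of actives in the top fraction of the pooled ranking.

    Entries are ranked ascending by score (best first), ties broken by
    compound_id; EF = (active fraction in the top ceil(f*N)) / (overall
    active fraction).
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    pooled = [(s, cid, True) for cid, s in actives.entries] + [
        (s, cid, False) for cid, s in decoys.entries
    ]
    if not pooled:
        raise ValueError("pooled set is empty")
    pooled.sort(key=lambda row: (row[0], row[1]))
    n = len(pooled)
    n_top = math.ceil(top_fraction * n)
    actives_in_top = sum(1 for row in pooled[:n_top] if row[2])
    prevalence = len(actives) / n
    ef = (actives_in_top / n_top) / prevalence if prevalence > 0 else 0.0
    return EnrichmentResult(top_fraction=top_fraction, ef=float(ef), n_top=n_top, actives_in_top=actives_in_top)
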