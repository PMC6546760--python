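"""Benchmark evaluation: ROC/AUC of the scorers on labelled SNV-sequence pairs.

Benchmark inputs follow the standard construction of an SNV centered in
its 101-nt context (50-nt flanks).  Both statistics are computed for a
sweep of half-window sizes; the dual-statistic intersection criterion is
evaluated by combining the two within-cohort ranks (a pair ranks high
only if it is high in both).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score, roc_curve

from .folding import FoldConfig, mutate_sequence, pairedness_profile
from .structure_diff import score_profiles

LABEL_POS = "riboSNitch"
LABEL_NEG = "non_riboSNitch"


class BenchmarkError(ValueError):
    pass


@dataclass(frozen=True)
class BenchmarkPair:
    pair_id: str
    sequence: str
    snv_pos: int
    ref: str
    alt: str
    label: str

    def __post_init__(self):
        n = len(self.sequence)
        if n % 2 == 0:
            raise BenchmarkError(f"{self.pair_id}: sequence length must be odd")
        if self.snv_pos != n // 2:
            raise BenchmarkError(f"{self.pair_id}: SNV must be centered")
        if self.sequence[self.snv_pos] != self.ref:
            raise BenchmarkError(f"{self.pair_id}: sequence[{self.snv_pos}] != ref")
        if self.ref == self.alt:
            raise BenchmarkError(f"{self.pair_id}: ref == alt")
        if self.label not in (LABEL_POS, LABEL_NEG):
            raise BenchmarkError(f"{self.pair_id}: unknown label {self.label!r}")

    @property
    def flank(self) -> int:
        return len(self.sequence) // 2


def score_benchmark(
    pairs: Sequence[BenchmarkPair],
    w: int,
    fold_config: FoldConfig = FoldConfig(),
) -> pd.DataFrame:
    """MeanDiff / EucDiff for every pair at half-window ``w``."""
    if not pairs:
        raise BenchmarkError("no benchmark pairs")
    flank = pairs[0].flank
    if w > flank:
        raise BenchmarkError(f"w={w} exceeds flank length {flank}")
    rows = []
    for p in pairs:
        ref_prof = pairedness_profile(p.sequence, fold_config, sequence_id=p.pair_id)
        alt_prof = pairedness_profile(
            mutate_sequence(p.sequence, p.snv_pos, p.alt), fold_config,
            sequence_id=p.pair_id + "|alt",
        )
        s = score_profiles(ref_prof.bpp, alt_prof.bpp, p.snv_pos, w,
                           mutation_key=p.pair_id)
        rows.append({
            "pair_id": p.pair_id,
            "mean_diff": s.mean_diff,
            "euc_diff": s.euc_diff,
            "label": p.label,
        })
    return pd.DataFrame(rows)


def roc_auc(scores, labels):
    """Rank-based AUC (ties averaged) with ROC curve points.

    Returns (auc, fpr, tpr); labels are positive for the riboSNitch class.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == LABEL_POS else 0 for l in labels])
    if len(set(y)) < 2:
        raise BenchmarkError("both labels must be present")
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, _ = roc_curve(y, scores)
    return auc, fpr, tpr


def intersection_auc(mean_scores, euc_scores, labels, strategy: str = "min_rank"):
    """AUC of the dual-statistic intersection ranking.

    'min_rank' ranks a pair by the smaller of its two within-cohort ranks,
    so it scores high only when high in both statistics; 'sum_rank' uses
    the rank sum.
    """
    mean_scores = np.asarray(mean_scores, dtype=float)
    euc_scores = np.asarray(euc_scores, dtype=float)
    if mean_scores.shape != euc_scores.shape:
        raise BenchmarkError("score vectors differ in length")
    rm = rankdata(mean_scores)
    re = rankdata(euc_scores)
    if strategy == "min_rank":
        combined = np.minimum(rm, re)
    elif strategy == "sum_rank":
        combined = rm + re
    else:
        raise BenchmarkError(f"unknown strategy {strategy!r}")
    auc, _, _ = roc_auc(combined, labels)
    return auc


def window_sweep(
    pairs: Sequence[BenchmarkPair],
    windows: Sequence[int] = (2, 5, 10, 15, 20, 25, 50),
    fold_config: FoldConfig = FoldConfig(),
) -> pd.DataFrame:
    """AUC of each statistic across a sweep of half-window sizes."""
    rows = []
    for w in windows:
        df = score_benchmark(pairs, w, fold_config)
        auc_m, _, _ = roc_auc(df["mean_diff"], df["label"])
        auc_e, _, _ = roc_auc(df["euc_diff"], df["label"])
        auc_i = intersection_auc(df["mean_diff"], df["euc_diff"], df["label"])
        rows.append({"w": w, "auc_mean_diff": auc_m, "auc_euc_diff": auc_e,
                     "auc_intersection": auc_i})
    return pd.DataFrame(rows)


def tail_classifier_stats(scores, labels, fraction: float = 0.05) -> dict:
    """Sensitivity/specificity of the discrete tail classifier.

    Calls the top ``fraction`` of scores positive and the bottom
    ``fraction`` negative (the benchmark protocol's tail convention) and
    reports the confusion on the called subset.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == LABEL_POS else 0 for l in labels])
    hi = np.quantile(scores, 1 - fraction)
    lo = np.quantile(scores, fraction)
    called_pos = scores >= hi
    called_neg = scores <= lo
    tp = int((called_pos & (y == 1)).sum())
    fp = int((called_pos & (y == 0)).sum())
    tn = int((called_neg & (y == 0)).sum())
    fn = int((called_neg & (y == 1)).sum())
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


BENCHMARK_COLUMNS = ["pair_id", "sequence", "snv_pos", "ref", "alt", "label"]


def write_benchmark_tsv(pairs: Sequence[BenchmarkPair], path):
    pd.DataFrame([
        {"pair_id": p.pair_id, "sequence": p.sequence, "snv_pos": p.snv_pos,
         "ref": p.ref, "alt": p.alt, "label": p.label}
        for p in pairs
    ], columns=BENCHMARK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_benchmark_tsv(path) -> list:
    df = pd.read_table(path, comment="#")
    return [
        BenchmarkPair(str(r.pair_id), r.sequence, int(r.snv_pos), r.ref, r.alt, r.label)
        for r in df.itertuples(index=False)
    ]
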