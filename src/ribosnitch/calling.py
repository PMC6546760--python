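"""Dual-tail riboSNitch calling.

A mutation is a riboSNitch when it lies in the top tail of *both*
MeanDiff and EucDiff over its cohort, a non-riboSNitch when it lies in
the bottom tail of both, and intermediate otherwise.  Thresholds are
empirical quantiles (linear interpolation); ties at a threshold are
included in the tail, so tail fractions can slightly exceed the nominal
value on discrete score distributions.  Cutoffs computed on one cohort
(e.g. a germline panel) can be exported and applied to another.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import numpy as np
import pandas as pd

LABEL_RIBO = "riboSNitch"
LABEL_NON = "non_riboSNitch"
LABEL_MID = "intermediate"


class CallingError(ValueError):
    pass


@dataclass(frozen=True)
class TailCutoffs:
    top_fraction: float
    bottom_fraction: float
    mean_top: float
    mean_bottom: float
    euc_top: float
    euc_bottom: float
    cohort_label: str = ""
    n_scores: int = 0

    def __post_init__(self):
        if self.mean_bottom > self.mean_top or self.euc_bottom > self.euc_top:
            raise CallingError("bottom threshold above top threshold")

    def to_file(self, path):
        with open(path, "w") as fh:
            for key, val in asdict(self).items():
                fh.write(f"{key}\t{val}\n")

    @classmethod
    def from_file(cls, path) -> "TailCutoffs":
        kv = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                key, val = line.rstrip("\n").split("\t", 1)
                kv[key] = val
        try:
            return cls(
                top_fraction=float(kv["top_fraction"]),
                bottom_fraction=float(kv["bottom_fraction"]),
                mean_top=float(kv["mean_top"]),
                mean_bottom=float(kv["mean_bottom"]),
                euc_top=float(kv["euc_top"]),
                euc_bottom=float(kv["euc_bottom"]),
                cohort_label=kv.get("cohort_label", ""),
                n_scores=int(kv.get("n_scores", 0)),
            )
        except KeyError as exc:
            raise CallingError(f"missing threshold {exc.args[0]!r} in {path}") from exc


def _score_arrays(scores):
    if isinstance(scores, pd.DataFrame):
        return scores["mean_diff"].to_numpy(float), scores["euc_diff"].to_numpy(float)
    mean = np.array([s.mean_diff for s in scores], dtype=float)
    euc = np.array([s.euc_diff for s in scores], dtype=float)
    return mean, euc


def compute_cutoffs(
    scores,
    top_fraction: float = 0.025,
    bottom_fraction: float = 0.025,
    cohort_label: str = "",
) -> TailCutoffs:
    """Empirical tail thresholds of MeanDiff and EucDiff for a cohort."""
    if not (0 < top_fraction < 0.5) or not (0 < bottom_fraction < 0.5):
        raise CallingError("tail fractions must lie in (0, 0.5)")
    mean, euc = _score_arrays(scores)
    if len(mean) == 0:
        raise CallingError("no scores")
    return TailCutoffs(
        top_fraction=top_fraction,
        bottom_fraction=bottom_fraction,
        mean_top=float(np.quantile(mean, 1 - top_fraction)),
        mean_bottom=float(np.quantile(mean, bottom_fraction)),
        euc_top=float(np.quantile(euc, 1 - top_fraction)),
        euc_bottom=float(np.quantile(euc, bottom_fraction)),
        cohort_label=cohort_label,
        n_scores=len(mean),
    )


def call(scores, cutoffs: TailCutoffs) -> np.ndarray:
    """Label each score riboSNitch / non_riboSNitch / intermediate.

    On degenerate distributions a score could fall in both tails; such
    scores are labelled intermediate rather than arbitrarily assigned.
    """
    mean, euc = _score_arrays(scores)
    ribo = (mean >= cutoffs.mean_top) & (euc >= cutoffs.euc_top)
    non = (mean <= cutoffs.mean_bottom) & (euc <= cutoffs.euc_bottom)
    both = ribo & non
    labels = np.full(len(mean), LABEL_MID, dtype=object)
    labels[ribo & ~both] = LABEL_RIBO
    labels[non & ~both] = LABEL_NON
    return labels


def apply_external_cutoffs(scores, external: TailCutoffs) -> np.ndarray:
    """Label a cohort with thresholds calibrated on another cohort."""
    if not external.cohort_label:
        raise CallingError("external cutoffs must carry a cohort_label")
    return call(scores, external)
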