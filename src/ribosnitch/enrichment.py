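"""Observed-vs-expected riboSNitch enrichment tests per transcript element.

For each element (a 5'UTR, 3'UTR or lncRNA) the observed riboSNitch
contingency is compared against the simulated expectation with one-sided
Fisher's exact tests in both directions; Benjamini-Hochberg correction is
applied within each (element class, direction) stratum.  Cancer
specificity compares the somatic contingency against a germline cohort
called with its own cutoffs and flags elements at P < 1e-3 (strict).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .calling import LABEL_RIBO, LABEL_NON

Q_CUTOFFS = (0.05, 0.1, 0.2)
CANCER_SPECIFIC_P = 1e-3


class EnrichmentError(ValueError):
    pass


def fisher_one_sided(a: int, b: int, c: int, d: int, direction: str) -> float:
    """One-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    direction 'enriched' tests whether the first row's success odds exceed
    the second row's ('greater'); 'depleted' tests the opposite tail.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise EnrichmentError(f"counts must be non-negative integers, got {x}")
    if direction not in ("enriched", "depleted"):
        raise EnrichmentError(f"unknown direction {direction!r}")
    alternative = "greater" if direction == "enriched" else "less"
    _, p = fisher_exact([[int(a), int(b)], [int(c), int(d)]], alternative=alternative)
    return float(min(p, 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any(pvals <= 0) or np.any(pvals > 1):
        raise EnrichmentError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c) with a Haldane 0.5 correction when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return float((a * d) / (b * c))


def cancer_specific(
    ribo_cancer: int, total_cancer: int,
    ribo_germline: int, total_germline: int,
    direction: str = "enriched",
    alpha: float = CANCER_SPECIFIC_P,
):
    """Test whether an element's riboSNitch load differs between cohorts.

    Each cohort must have been called with its own cutoffs.  Returns
    (p, is_specific) with is_specific = (p < alpha), strict.
    """
    if total_cancer == 0 or total_germline == 0:
        return 1.0, False
    p = fisher_one_sided(
        ribo_cancer, total_cancer - ribo_cancer,
        ribo_germline, total_germline - ribo_germline,
        direction,
    )
    return p, bool(p < alpha)


def test_elements(
    observed: pd.DataFrame,
    expected: pd.DataFrame,
    germline: Optional[pd.DataFrame] = None,
    q_cutoffs: Sequence[float] = Q_CUTOFFS,
) -> pd.DataFrame:
    """Directional enrichment tests for every element.

    ``observed`` and ``expected`` need columns element_id, element_class,
    and (obs_ribo, obs_total) / (exp_ribo, exp_total); optional
    ``germline`` adds (gl_ribo, gl_total) per element_id for the
    cancer-specificity test.  Elements present in only one cohort are
    excluded and flagged in the 'flag' column of the returned frame.
    BH correction is applied within each (element_class, direction)
    stratum.
    """
    for frame, cols in ((observed, ("obs_ribo", "obs_total")),
                        (expected, ("exp_ribo", "exp_total"))):
        missing = {"element_id", "element_class", *cols} - set(frame.columns)
        if missing:
            raise EnrichmentError(f"missing columns {sorted(missing)}")
    merged = observed.merge(
        expected.drop(columns=["element_class"]), on="element_id", how="outer",
        indicator=True,
    )
    merged["flag"] = merged["_merge"].map({
        "both": "", "left_only": "missing_expected", "right_only": "missing_observed",
    }).astype(str)
    results = merged[merged["flag"] == ""].drop(columns=["_merge"]).copy()
    dropped = merged[merged["flag"] != ""][["element_id", "flag"]]

    rows = []
    for r in results.itertuples(index=False):
        a = int(r.obs_ribo)
        b = int(r.obs_total) - a
        c = int(r.exp_ribo)
        d = int(r.exp_total) - c
        if b < 0 or d < 0:
            raise EnrichmentError(f"ribo count exceeds total for {r.element_id}")
        rows.append({
            "element_id": r.element_id,
            "element_class": r.element_class,
            "obs_ribo": a, "obs_total": int(r.obs_total),
            "exp_ribo": c, "exp_total": int(r.exp_total),
            "odds_ratio": odds_ratio(a, b, c, d),
            "p_enriched": fisher_one_sided(a, b, c, d, "enriched"),
            "p_depleted": fisher_one_sided(a, b, c, d, "depleted"),
        })
    out = pd.DataFrame(rows, columns=[
        "element_id", "element_class", "obs_ribo", "obs_total",
        "exp_ribo", "exp_total", "odds_ratio", "p_enriched", "p_depleted",
    ])
    out["q_enriched"] = np.nan
    out["q_depleted"] = np.nan
    for cls, idx in out.groupby("element_class").groups.items():
        out.loc[idx, "q_enriched"] = bh_adjust(out.loc[idx, "p_enriched"].to_numpy())
        out.loc[idx, "q_depleted"] = bh_adjust(out.loc[idx, "p_depleted"].to_numpy())
    for q in q_cutoffs:
        col = f"call_q{str(q).replace('0.', '')}"
        out[col] = np.where(
            out["q_enriched"] < q, "enriched",
            np.where(out["q_depleted"] < q, "depleted", "none"),
        )
    if germline is not None:
        gl = germline.set_index("element_id")
        cs_p, cs_flag = [], []
        for r in out.itertuples(index=False):
            if r.element_id not in gl.index:
                cs_p.append(np.nan)
                cs_flag.append(False)
                continue
            g = gl.loc[r.element_id]
            direction = "enriched" if r.p_enriched <= r.p_depleted else "depleted"
            p, flag = cancer_specific(
                r.obs_ribo, r.obs_total, int(g["gl_ribo"]), int(g["gl_total"]),
                direction=direction,
            )
            cs_p.append(p)
            cs_flag.append(flag)
        out["cancer_specific_p"] = cs_p
        out["cancer_specific"] = cs_flag
    if len(dropped):
        out = pd.concat([out, dropped], ignore_index=True)
        out["flag"] = out["flag"].fillna("")
    else:
        out["flag"] = ""
    return out


# library API, not a pytest case (the name would otherwise be collected
# when imported into a test module)
test_elements.__test__ = False


def element_counts(scores: pd.DataFrame, labels, element_col: str = "element_id",
                   class_col: str = "element_class",
                   prefix: str = "obs") -> pd.DataFrame:
    """Aggregate riboSNitch / total counts per element from labelled scores."""
    df = scores.copy()
    df["label"] = labels
    grouped = df.groupby([element_col, class_col], as_index=False).agg(
        ribo=("label", lambda s: int((s == LABEL_RIBO).sum())),
        total=("label", "size"),
    )
    return grouped.rename(columns={
        "ribo": f"{prefix}_ribo", "total": f"{prefix}_total",
    })


def feature_overlap_enrichment(
    calls: pd.DataFrame,
    features,
    pad: int = 20,
    direction: str = "enriched",
):
    """Are riboSNitches over-represented in (padded) binding-site intervals?

    ``calls`` needs columns chrom, pos (1-based), label; ``features`` is a
    BED path or (chrom, start, end) tuples.  Intervals are padded by
    ``pad`` nt on each side; the 2x2 Fisher table is riboSNitch vs
    non-riboSNitch x inside vs outside (intermediate calls are ignored).
    """
    from intervaltree import IntervalTree
    from .annotation import read_bed
    from pathlib import Path

    if isinstance(features, (str, Path)):
        features = read_bed(features)
    labelled = calls[calls["label"].isin([LABEL_RIBO, LABEL_NON])]
    if labelled.empty:
        raise EnrichmentError("no riboSNitch / non-riboSNitch calls to test")
    trees = {}
    for chrom, start, end in features:
        s, e = max(0, start - pad), end + pad
        if e > s:
            trees.setdefault(chrom, IntervalTree()).addi(s, e)
    inside = labelled.apply(
        lambda r: r["chrom"] in trees and trees[r["chrom"]].overlaps_point(r["pos"] - 1),
        axis=1,
    )
    is_ribo = labelled["label"] == LABEL_RIBO
    a = int((is_ribo & inside).sum())
    b = int((is_ribo & ~inside).sum())
    c = int((~is_ribo & inside).sum())
    d = int((~is_ribo & ~inside).sum())
    return odds_ratio(a, b, c, d), fisher_one_sided(a, b, c, d, direction)


def plot_manhattan(results: pd.DataFrame, path, direction: str = "enriched",
                   q_cutoff: float = 0.05):
    """Simple per-class Manhattan-style plot of -log10 p-values."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    col = f"p_{direction}"
    df = results[results["flag"] == ""].reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(8, 3))
    for i, (cls, sub) in enumerate(df.groupby("element_class")):
        ax.scatter(sub.index, -np.log10(sub[col]), s=12, label=cls)
    ax.axhline(-np.log10(q_cutoff), ls="--", c="grey", lw=0.8)
    ax.set_ylabel(f"-log10 p ({direction})")
    ax.set_xticks([])
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
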