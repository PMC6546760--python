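"""MeanDiff and EucDiff: windowed distances between pairedness profiles.

For a mutation at mature position ``k`` and half-window ``w``::

    MeanDiff = mean_{i in [k-w, k+w]} |bpp_ref[i] - bpp_alt[i]|
    EucDiff  = sqrt( sum_{i in [k-w, k+w]} (bpp_ref[i] - bpp_alt[i])^2 )

Windows reaching past a transcript end are clipped and MeanDiff is
normalised by the number of positions actually summed, so it remains an
average for mutations near the ends; ``effective_positions`` records that
count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import MappedMutation
from .folding import FoldConfig, PairednessProfile, mutate_sequence, pairedness_profile


class ScoreError(ValueError):
    pass


@dataclass(frozen=True)
class StructureDiffScore:
    mutation_key: str
    transcript_id: str
    k: int
    w: int
    effective_positions: int
    mean_diff: float
    euc_diff: float
    region: Optional[str] = None
    origin: str = "observed"


def _window(bpp_ref, bpp_alt, k: int, w: int):
    ref = np.asarray(bpp_ref, dtype=float)
    alt = np.asarray(bpp_alt, dtype=float)
    if ref.shape != alt.shape:
        raise ScoreError(f"profile length mismatch: {ref.shape} vs {alt.shape}")
    n = len(ref)
    if not (0 <= k < n):
        raise ScoreError(f"mutation position {k} outside profile of length {n}")
    if w < 0:
        raise ScoreError("half-window w must be >= 0")
    lo, hi = max(0, k - w), min(n - 1, k + w)
    return ref[lo:hi + 1] - alt[lo:hi + 1]


def mean_diff(bpp_ref, bpp_alt, k: int, w: int) -> float:
    d = _window(bpp_ref, bpp_alt, k, w)
    return float(np.abs(d).mean())


def euc_diff(bpp_ref, bpp_alt, k: int, w: int) -> float:
    d = _window(bpp_ref, bpp_alt, k, w)
    return float(np.sqrt((d * d).sum()))


def effective_positions(n: int, k: int, w: int) -> int:
    return min(n - 1, k + w) - max(0, k - w) + 1


def score_profiles(
    bpp_ref, bpp_alt, k: int, w: int,
    mutation_key: str = "", transcript_id: str = "",
    region: Optional[str] = None, origin: str = "observed",
) -> StructureDiffScore:
    d = _window(bpp_ref, bpp_alt, k, w)
    return StructureDiffScore(
        mutation_key=mutation_key,
        transcript_id=transcript_id,
        k=k,
        w=w,
        effective_positions=len(d),
        mean_diff=float(np.abs(d).mean()),
        euc_diff=float(np.sqrt((d * d).sum())),
        region=region,
        origin=origin,
    )


def score_mutation(
    mapped: MappedMutation,
    transcript_seq: str,
    fold_config: FoldConfig = FoldConfig(),
    w: int = 50,
    ref_profile: Optional[PairednessProfile] = None,
) -> StructureDiffScore:
    """Fold reference and mutated mature sequence and score the difference.

    ``ref_profile`` may be passed to reuse the reference fold across all
    mutations of one transcript.
    """
    if mapped.k is None:
        raise ScoreError(f"mutation {mapped.record.key} is not exonic")
    if ref_profile is None:
        ref_profile = pairedness_profile(transcript_seq, fold_config,
                                         sequence_id=mapped.transcript_id)
    if len(ref_profile) != len(transcript_seq):
        raise ScoreError("reference profile does not match transcript length")
    alt_seq = mutate_sequence(transcript_seq, mapped.k, mapped.alt_t)
    alt_profile = pairedness_profile(alt_seq, fold_config,
                                     sequence_id=mapped.transcript_id + "|alt")
    return score_profiles(
        ref_profile.bpp, alt_profile.bpp, mapped.k, w,
        mutation_key=mapped.record.key,
        transcript_id=mapped.transcript_id,
        region=mapped.region,
    )


def score_transcript_mutations(
    mapped_mutations: Sequence[MappedMutation],
    transcript_seq: str,
    fold_config: FoldConfig = FoldConfig(),
    w: int = 50,
) -> list:
    """Score all mutations of one transcript, folding the reference once."""
    if not mapped_mutations:
        return []
    tid = mapped_mutations[0].transcript_id
    ref_profile = pairedness_profile(transcript_seq, fold_config, sequence_id=tid)
    return [
        score_mutation(m, transcript_seq, fold_config, w, ref_profile=ref_profile)
        for m in mapped_mutations
    ]


SCORE_COLUMNS = [
    "mutation_key", "transcript_id", "k", "region", "mean_diff", "euc_diff",
    "w", "effective_positions", "origin",
]


def scores_to_frame(scores: Sequence[StructureDiffScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mutation_key": s.mutation_key,
                "transcript_id": s.transcript_id,
                "k": s.k,
                "region": s.region,
                "mean_diff": s.mean_diff,
                "euc_diff": s.euc_diff,
                "w": s.w,
                "effective_positions": s.effective_positions,
                "origin": s.origin,
            }
            for s in scores
        ],
        columns=SCORE_COLUMNS,
    )


def write_scores(df: pd.DataFrame, path, header_comment: Optional[str] = None):
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_scores(path) -> pd.DataFrame:
    return pd.read_table(path, comment="#")
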