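"""Neutral mutation model from intronic trinucleotide mutation profiles.

Intronic mutations are assumed close to selectively neutral, so their
96-class substitution spectrum serves as the background mutation process.
For each transcript the 96-class profile is recalibrated by the
transcript's own 32-class trinucleotide composition, giving a per-class
sampling distribution from which randomised mutation cohorts are drawn
and scored exactly like observed mutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    BASES,
    N_CONTEXT_CLASSES,
    N_SUBSTITUTION_CLASSES,
    MappedMutation,
    class32_label,
    class96_alleles,
    class96_label,
    classify_position,
    complement,
    context_class_of,
)
from .folding import FoldConfig, mutate_sequence, pairedness_profile
from .structure_diff import StructureDiffScore, score_profiles
from .calling import compute_cutoffs, call, LABEL_RIBO


class NeutralModelError(ValueError):
    pass


@dataclass
class MutationProfile96:
    """96-class background mutation profile.

    ``frequency`` normalisation sums to 1; ``per_context_rate`` divides
    each class count by the number of occurrences of its trinucleotide
    context in the source (intronic) sequence.
    """

    rate: np.ndarray
    normalization: str
    source_cohort: str = ""

    def __post_init__(self):
        self.rate = np.asarray(self.rate, dtype=float)
        if self.rate.shape != (N_SUBSTITUTION_CLASSES,):
            raise NeutralModelError("profile must have 96 entries")
        if np.any(self.rate < 0):
            raise NeutralModelError("rates must be non-negative")
        if self.normalization not in ("frequency", "per_context_rate"):
            raise NeutralModelError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "frequency":
            total = self.rate.sum()
            if not np.isclose(total, 1.0, atol=1e-9):
                raise NeutralModelError(f"frequency profile sums to {total}, not 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class96": np.arange(N_SUBSTITUTION_CLASSES),
            "label": [class96_label(c) for c in range(N_SUBSTITUTION_CLASSES)],
            "rate": self.rate,
        })


@dataclass
class TriComposition32:
    count: np.ndarray

    def __post_init__(self):
        self.count = np.asarray(self.count)
        if self.count.shape != (N_CONTEXT_CLASSES,):
            raise NeutralModelError("composition must have 32 entries")
        if np.any(self.count < 0):
            raise NeutralModelError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class32": np.arange(N_CONTEXT_CLASSES),
            "label": [class32_label(c) for c in range(N_CONTEXT_CLASSES)],
            "count": self.count,
        })


@dataclass
class RandomizationResult:
    transcript_id: str
    R: int
    expected_ribo: int
    expected_total: int
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0 <= self.expected_ribo <= self.expected_total):
            raise NeutralModelError("expected_ribo must lie in [0, expected_total]")


# ---------------------------------------------------------------------------


def build_profile(
    intronic_mutations: Sequence[MappedMutation],
    intronic_context_counts,
    normalization: str = "per_context_rate",
    source_cohort: str = "",
) -> MutationProfile96:
    """96-class profile from intronic mutations and intronic context counts."""
    if isinstance(intronic_context_counts, TriComposition32):
        intronic_context_counts = intronic_context_counts.count
    ctx = np.asarray(intronic_context_counts, dtype=float)
    if ctx.shape != (N_CONTEXT_CLASSES,):
        raise NeutralModelError("context counts must have 32 entries")
    counts = np.zeros(N_SUBSTITUTION_CLASSES)
    for m in intronic_mutations:
        if m.subst_class96 is None:
            continue
        counts[m.subst_class96] += 1
    if counts.sum() == 0:
        raise NeutralModelError("no classifiable intronic mutations")
    if normalization == "frequency":
        return MutationProfile96(counts / counts.sum(), "frequency", source_cohort)
    rate = np.zeros(N_SUBSTITUTION_CLASSES)
    for c in range(N_SUBSTITUTION_CLASSES):
        if counts[c] == 0:
            continue
        denom = ctx[context_class_of(c)]
        if denom <= 0:
            raise NeutralModelError(
                f"observed mutations in class {class96_label(c)} but its context "
                "count is zero"
            )
        rate[c] = counts[c] / denom
    return MutationProfile96(rate, "per_context_rate", source_cohort)


def transcript_composition(sequence: str, positions=None) -> TriComposition32:
    """32-class trinucleotide composition of a sequence.

    Slides a 3-mer window over the sequence (so the first and last base
    have no context), strand-collapses the center to a pyrimidine and
    counts per class; 3-mers containing N are skipped.  ``positions``
    optionally restricts counting to a subset of center positions.
    """
    if len(sequence) < 3:
        raise NeutralModelError("sequence shorter than 3 has no trinucleotide context")
    if positions is None:
        positions = range(1, len(sequence) - 1)
    count = np.zeros(N_CONTEXT_CLASSES, dtype=int)
    for k in positions:
        c32 = classify_position(sequence, k)
        if c32 is not None:
            count[c32] += 1
    return TriComposition32(count)


def recalibrate(profile: MutationProfile96, composition: TriComposition32) -> np.ndarray:
    """Per-class sampling distribution for one transcript.

    P(class c) is proportional to rate[c] x composition[context(c)];
    classes whose context is absent from the transcript get probability 0.
    """
    weights = np.array([
        profile.rate[c] * composition.count[context_class_of(c)]
        for c in range(N_SUBSTITUTION_CLASSES)
    ], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise NeutralModelError("transcript incompatible with profile (all-zero product)")
    return weights / total


def site_index(sequence: str, positions=None) -> dict:
    """Map 32-class -> array of center positions in the sequence."""
    if positions is None:
        positions = range(1, len(sequence) - 1)
    index: dict = {}
    for k in positions:
        c32 = classify_position(sequence, k)
        if c32 is not None:
            index.setdefault(c32, []).append(k)
    return {c: np.asarray(ks, dtype=int) for c, ks in index.items()}


def _alt_allele_at(sequence: str, k: int, c96: int) -> str:
    """Actual alt base at position k implied by a (collapsed) 96-class."""
    _, alt_pyr = class96_alleles(c96)
    return complement(alt_pyr) if sequence[k] in "AG" else alt_pyr


def sample_mutations(
    sequence: str,
    distribution: np.ndarray,
    n: int,
    rng: np.random.Generator,
    positions=None,
    max_retries: int = 100,
) -> list:
    """Draw n (k, ref, alt, class96) substitutions from a 96-class distribution.

    Each draw picks a class, then a uniform site among positions matching
    the class's trinucleotide context, then the implied alt allele.
    Classes without a matching site trigger a bounded redraw (they have
    probability 0 when the distribution was recalibrated against the same
    position set, so retries only matter for mismatched inputs).
    """
    distribution = np.asarray(distribution, dtype=float)
    index = site_index(sequence, positions)
    out = []
    for _ in range(n):
        for attempt in range(max_retries):
            c96 = int(rng.choice(N_SUBSTITUTION_CLASSES, p=distribution))
            sites = index.get(context_class_of(c96))
            if sites is not None and len(sites):
                break
        else:
            raise NeutralModelError(
                "drawn class has no matching site after bounded retries"
            )
        k = int(sites[rng.integers(len(sites))])
        out.append((k, sequence[k], _alt_allele_at(sequence, k, c96), c96))
    return out


def simulate(
    transcript_id: str,
    sequence: str,
    distribution: np.ndarray,
    R: int = 1000,
    rng=None,
    seed: Optional[int] = None,
    fold_config: FoldConfig = FoldConfig(),
    w: int = 50,
    positions=None,
) -> list:
    """Score R random neutral mutations of one transcript.

    Returns StructureDiffScores with origin='simulated'; the reference
    fold is computed once and reused.
    """
    if R < 1:
        raise NeutralModelError("R must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = sample_mutations(sequence, distribution, R, rng, positions)
    ref_profile = pairedness_profile(sequence, fold_config, sequence_id=transcript_id)
    scores = []
    for idx, (k, ref, alt, c96) in enumerate(draws):
        alt_profile = pairedness_profile(
            mutate_sequence(sequence, k, alt), fold_config,
            sequence_id=f"{transcript_id}|sim{idx}",
        )
        scores.append(score_profiles(
            ref_profile.bpp, alt_profile.bpp, k, w,
            mutation_key=f"sim:{transcript_id}:{idx}:{k}:{ref}>{alt}",
            transcript_id=transcript_id,
            origin="simulated",
        ))
    return scores


def expected_ribo_count(
    simulated_scores: pd.DataFrame,
    top_fraction: float = 0.025,
    bottom_fraction: float = 0.025,
):
    """riboSNitch calls on the pooled simulated cohort.

    Cutoffs are computed on the pooled simulated score distribution (not
    imported from the observed cohort) and applied back to each
    transcript's simulated mutations.  Returns (cutoffs, labels,
    per-transcript DataFrame with expected_ribo / expected_total).
    """
    cutoffs = compute_cutoffs(
        simulated_scores, top_fraction, bottom_fraction, cohort_label="simulated",
    )
    labels = call(simulated_scores, cutoffs)
    df = simulated_scores.copy()
    df["label"] = labels
    per = df.groupby("transcript_id").agg(
        expected_ribo=("label", lambda s: int((s == LABEL_RIBO).sum())),
        expected_total=("label", "size"),
    ).reset_index()
    per_transcript = [
        RandomizationResult(
            transcript_id=r.transcript_id,
            R=int(r.expected_total),
            expected_ribo=int(r.expected_ribo),
            expected_total=int(r.expected_total),
        )
        for r in per.itertuples(index=False)
    ]
    return cutoffs, labels, per, per_transcript
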