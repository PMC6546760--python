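"""Per-position base-pairedness probabilities from a pluggable folding backend.

The internal backend is a pair-weight partition function over all
pseudoknot-free secondary structures with canonical pairs (AU, GC, GU),
a minimal hairpin loop, and a maximal base-pair span: each structure is
weighted ``pair_weight ** n_pairs`` (the ``stack`` model adds a bonus
factor per stacked helix pair).  Pair probabilities are computed exactly
by inside-outside recursions and can be verified against exhaustive
structure enumeration on short sequences.  It is deliberately not a
nearest-neighbour thermodynamic model: it exists so every number the
pipeline produces can be checked by brute force.  The adapter backend
reads RNAplfold-style per-position unpaired probabilities (``-u 1``
output) for runs that want a full energy model upstream.

Sequences longer than the local-folding window are handled RNAplfold
style: every length-``window_W`` window is folded independently and
per-position pairedness is averaged over all windows covering the
position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numba import njit

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
#: canonical pairs incl. the GU wobble, on the DNA alphabet used internally
_CANONICAL = {(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)}

_ENUM_GUARD = 20


class FoldingError(ValueError):
    pass


@dataclass(frozen=True)
class FoldConfig:
    """Folding parameters.

    window_W: local folding window (nt); sequences longer than this are
        folded in sliding windows and averaged.
    max_span_L: maximal i..j span of a base pair; defaults to window_W.
    min_hairpin: minimal number of unpaired bases in a hairpin loop.
    pair_weight_model: 'uniform' (constant weight per pair) or 'stack'
        (extra bonus for each pair stacked directly on another).  The
        stack model is the default: rewarding contiguous helices makes
        single mismatches genuinely destabilising, mirroring the helix
        cooperativity of real nearest-neighbour energetics; the uniform
        model is robust to slippage re-pairing and is mainly useful as
        the simplest enumeration-checkable reference.
    pair_weight: multiplicative Boltzmann weight per base pair.
    stack_bonus: extra factor per stacked pair (stack model only).
    backend: 'internal' or 'rnaplfold_adapter'.
    """

    window_W: int = 200
    max_span_L: Optional[int] = None
    min_hairpin: int = 3
    pair_weight_model: str = "stack"
    pair_weight: float = 2.0
    stack_bonus: float = 3.0
    backend: str = "internal"

    def __post_init__(self):
        if self.window_W < 1:
            raise FoldingError("window_W must be >= 1")
        span = self.span
        if not (1 <= span <= self.window_W):
            raise FoldingError("need 1 <= max_span_L <= window_W")
        if self.min_hairpin < 0:
            raise FoldingError("min_hairpin must be >= 0")
        if self.pair_weight_model not in ("uniform", "stack"):
            raise FoldingError(f"unknown pair_weight_model {self.pair_weight_model!r}")
        if self.pair_weight <= 0 or self.stack_bonus <= 0:
            raise FoldingError("weights must be positive")
        if self.backend not in ("internal", "rnaplfold_adapter"):
            raise FoldingError(f"unknown backend {self.backend!r}")

    @property
    def span(self) -> int:
        return self.window_W if self.max_span_L is None else self.max_span_L

    @property
    def stack_factor(self) -> float:
        return self.stack_bonus if self.pair_weight_model == "stack" else 1.0


@dataclass
class PairednessProfile:
    """Per-position probability of being base-paired."""

    sequence_id: str
    bpp: np.ndarray

    def __post_init__(self):
        self.bpp = np.asarray(self.bpp, dtype=float)
        if self.bpp.ndim != 1:
            raise FoldingError("bpp must be a 1-D vector")
        if np.any(self.bpp < -1e-9) or np.any(self.bpp > 1 + 1e-9):
            raise FoldingError("bpp entries must lie in [0, 1]")
        self.bpp = np.clip(self.bpp, 0.0, 1.0)

    def __len__(self):
        return len(self.bpp)


def encode_sequence(sequence: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in sequence.upper()], dtype=np.int8)
    except KeyError as exc:
        raise FoldingError(f"non-ACGTN base {exc.args[0]!r} in sequence") from exc


def _pairable_matrix(codes: np.ndarray) -> np.ndarray:
    n = len(codes)
    ok = np.zeros((n, n), dtype=np.bool_)
    for i in range(n):
        for j in range(n):
            if (int(codes[i]), int(codes[j])) in _CANONICAL:
                ok[i, j] = True
    return ok


# ---------------------------------------------------------------------------
# inside-outside kernels
#
# Z[i, j]  : partition function of subsequence [i, j) (half-open)
# Zb[i, j] : partition function of [i, j) given that i pairs with j-1
# Grammar:  Z[i,j] = Z[i+1,j] + sum_m Zb[i,m] * Z[m,j]
#           Zb[i,j] = w * (Z[i+1,j-1] + (s-1) * Zb[i+1,j-1])
# The outside pass propagates context weights OS/OP down the same rules;
# P(pair (i, j-1)) = Zb[i,j] * OP[i,j] / Z[0,n].


@njit(cache=True)
def _inside(pairok, w, s, minhp, maxspan):  # pragma: no cover - numba
    n = pairok.shape[0]
    Z = np.zeros((n + 1, n + 1))
    Zb = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        Z[i, i] = 1.0
    for d in range(1, n + 1):
        for i in range(0, n - d + 1):
            j = i + d
            if (
                d >= 2
                and pairok[i, j - 1]
                and d - 2 >= minhp
                and d - 1 <= maxspan
            ):
                inner = Z[i + 1, j - 1]
                if s != 1.0:
                    inner += (s - 1.0) * Zb[i + 1, j - 1]
                Zb[i, j] = w * inner
            acc = Z[i + 1, j]
            for m in range(i + 2, j + 1):
                if Zb[i, m] > 0.0:
                    acc += Zb[i, m] * Z[m, j]
            Z[i, j] = acc
    return Z, Zb


@njit(cache=True)
def _outside(Z, Zb, w, s, n):  # pragma: no cover - numba
    OS = np.zeros((n + 1, n + 1))
    OP = np.zeros((n + 1, n + 1))
    OS[0, n] = 1.0
    for d in range(n, 0, -1):
        for i in range(0, n - d + 1):
            j = i + d
            os_ij = OS[i, j]
            if os_ij > 0.0:
                OS[i + 1, j] += os_ij
                for m in range(i + 2, j + 1):
                    if Zb[i, m] > 0.0:
                        OP[i, m] += os_ij * Z[m, j]
                        OS[m, j] += os_ij * Zb[i, m]
        for i in range(0, n - d + 1):
            j = i + d
            op = OP[i, j]
            if op > 0.0 and Zb[i, j] > 0.0:
                OS[i + 1, j - 1] += op * w
                if s != 1.0:
                    OP[i + 1, j - 1] += op * w * (s - 1.0)
    return OS, OP


def pair_probability_matrix(sequence: str, config: FoldConfig) -> np.ndarray:
    """Exact P(i pairs j) matrix for a sequence folded as one window."""
    codes = encode_sequence(sequence)
    n = len(codes)
    if n == 0:
        raise FoldingError("empty sequence")
    pairok = _pairable_matrix(codes)
    w = float(config.pair_weight)
    s = float(config.stack_factor)
    Z, Zb = _inside(pairok, w, s, config.min_hairpin, config.span)
    OS, OP = _outside(Z, Zb, w, s, n)
    total = Z[0, n]
    P = np.zeros((n, n))
    with np.errstate(invalid="ignore"):
        M = Zb * OP / total
    for i in range(n):
        for j in range(i + 1, n + 1):
            if M[i, j] > 0.0:
                P[i, j - 1] = M[i, j]
    return P


def _bpp_single_window(sequence: str, config: FoldConfig) -> np.ndarray:
    P = pair_probability_matrix(sequence, config)
    return np.clip(P.sum(axis=0) + P.sum(axis=1), 0.0, 1.0)


def pairedness_profile(
    sequence: str,
    config: FoldConfig = FoldConfig(),
    sequence_id: str = "seq",
    lunp_path=None,
) -> PairednessProfile:
    """Per-position paired probability ``bpp[i] = sum_j P(i, j)``.

    With the internal backend, sequences longer than ``window_W`` are
    folded in all sliding windows of that length and the per-position
    values averaged over the windows covering each position.  With the
    ``rnaplfold_adapter`` backend, ``lunp_path`` must point to an
    RNAplfold ``_lunp`` unpaired-probability file for this sequence.
    """
    if len(sequence) == 0:
        raise FoldingError("empty sequence")
    if config.backend == "rnaplfold_adapter":
        if lunp_path is None:
            raise FoldingError("rnaplfold_adapter backend requires lunp_path")
        profile = profile_from_rnaplfold(lunp_path, sequence_id=sequence_id)
        if len(profile) != len(sequence):
            raise FoldingError(
                f"lunp file has {len(profile)} positions, sequence has {len(sequence)}"
            )
        return profile
    n = len(sequence)
    W = config.window_W
    if n <= W:
        bpp = _bpp_single_window(sequence, config)
    else:
        acc = np.zeros(n)
        cover = np.zeros(n)
        for t in range(n - W + 1):
            acc[t:t + W] += _bpp_single_window(sequence[t:t + W], config)
            cover[t:t + W] += 1
        bpp = acc / cover
    return PairednessProfile(sequence_id, bpp)


def mutate_sequence(sequence: str, k: int, alt: str) -> str:
    """Return a copy of ``sequence`` with position ``k`` replaced by ``alt``."""
    if not (0 <= k < len(sequence)):
        raise FoldingError(f"position {k} outside sequence of length {len(sequence)}")
    alt = alt.upper()
    if alt not in "ACGTN":
        raise FoldingError(f"bad alt allele {alt!r}")
    if sequence[k].upper() == alt:
        raise FoldingError(f"not a variant: base at {k} already {alt}")
    return sequence[:k] + alt + sequence[k + 1:]


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle (exported: the internal backend is tested
# against it, and callers may use it for their own verification)


def enumerate_structures(sequence: str, config: FoldConfig = FoldConfig()):
    """All pseudoknot-free structures of a short sequence with their weights.

    Returns a list of ``(pairs, weight)`` where ``pairs`` is a sorted tuple
    of (i, j) base pairs.  The empty structure is always present.  Guarded
    to ``len(sequence) <= 20``.
    """
    n = len(sequence)
    if n > _ENUM_GUARD:
        raise FoldingError(f"enumeration limited to n <= {_ENUM_GUARD} (got {n})")
    if n == 0:
        raise FoldingError("empty sequence")
    codes = encode_sequence(sequence)
    pairok = _pairable_matrix(codes)
    minhp, maxspan = config.min_hairpin, config.span
    memo = {}

    def rec(i, j):  # structures of closed interval [i, j]
        if i >= j:
            return [()]
        if (i, j) in memo:
            return memo[(i, j)]
        out = [st for st in rec(i + 1, j)]
        for l in range(i + 1, j + 1):
            if (
                pairok[i, l]
                and (l - i - 1) >= minhp
                and (l - i) <= maxspan
            ):
                for inner in rec(i + 1, l - 1):
                    for outer in rec(l + 1, j):
                        out.append(((i, l),) + inner + outer)
        memo[(i, j)] = out
        return out

    w = float(config.pair_weight)
    s = float(config.stack_factor)
    results = []
    for st in rec(0, n - 1):
        pairs = tuple(sorted(st))
        weight = w ** len(pairs)
        if s != 1.0 and pairs:
            pairset = set(pairs)
            stacked = sum(1 for (a, b) in pairs if (a + 1, b - 1) in pairset)
            weight *= s ** stacked
        results.append((pairs, weight))
    return results


def bpp_from_enumeration(sequence: str, config: FoldConfig = FoldConfig()) -> np.ndarray:
    """Per-position paired probability by brute-force enumeration."""
    structures = enumerate_structures(sequence, config)
    total = sum(wt for _, wt in structures)
    bpp = np.zeros(len(sequence))
    for pairs, wt in structures:
        for i, j in pairs:
            bpp[i] += wt
            bpp[j] += wt
    return bpp / total


def partition_from_enumeration(sequence: str, config: FoldConfig = FoldConfig()) -> float:
    return sum(wt for _, wt in enumerate_structures(sequence, config))


def partition_function(sequence: str, config: FoldConfig = FoldConfig()) -> float:
    """Partition function of a single-window fold (internal backend)."""
    codes = encode_sequence(sequence)
    pairok = _pairable_matrix(codes)
    Z, _ = _inside(
        pairok, float(config.pair_weight), float(config.stack_factor),
        config.min_hairpin, config.span,
    )
    return float(Z[0, len(codes)])


# ---------------------------------------------------------------------------
# RNAplfold adapter


def read_rnaplfold_lunp(path) -> np.ndarray:
    """Parse an RNAplfold ``_lunp`` file and return P(unpaired) for u = 1.

    The format is: comment lines starting with '#', then one row per
    position with the 1-based position followed by unpaired probabilities
    for span u = 1, 2, ...; only the u = 1 column is used.
    """
    probs = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FoldingError(f"{path}:{lineno}: expected >= 2 columns")
            try:
                pos = int(parts[0])
                p = float(parts[1])
            except ValueError as exc:
                raise FoldingError(f"{path}:{lineno}: malformed row {line!r}") from exc
            if not (0.0 <= p <= 1.0):
                raise FoldingError(f"{path}:{lineno}: probability {p} outside [0,1]")
            if pos < 1 or pos in probs:
                raise FoldingError(f"{path}:{lineno}: bad or duplicate position {pos}")
            probs[pos] = p
    if not probs:
        raise FoldingError(f"{path}: no data rows")
    n = max(probs)
    if sorted(probs) != list(range(1, n + 1)):
        raise FoldingError(f"{path}: positions are not contiguous from 1")
    return np.array([probs[i] for i in range(1, n + 1)])


def profile_from_rnaplfold(path, sequence_id: str = "seq") -> PairednessProfile:
    """Pairedness profile from RNAplfold output: bpp[i] = 1 - P(unpaired)."""
    return PairednessProfile(sequence_id, 1.0 - read_rnaplfold_lunp(path))
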