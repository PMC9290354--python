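"""Pairwise local alignment and ungapped Karlin-Altschul statistics.

The local aligner is a word-seeded Smith-Waterman with affine gaps: a pair of
sequences is considered at all only if the two share an exact word of
``word_size`` nucleotides (the seed filter); scoring of surviving pairs is by
exact dynamic programming, so a seeded score can never exceed the exhaustive
one and equals it whenever any exact seed exists.  ``N`` never matches.

E-values follow the ungapped Karlin-Altschul theory, E = K*m*n*exp(-lambda*S),
with (lambda, K) derived numerically for the configured match/mismatch scheme
(uniform base composition).  This is an approximation for gapped scores; the
hit thresholds are configurable to compensate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit
from scipy.optimize import brentq

__all__ = [
    "Scoring",
    "LocalAlignment",
    "local_align",
    "shared_words",
    "karlin_altschul_params",
    "evalue",
]

_NEG = -(10**9)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "U": 3}


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring scheme.  A gap of length L costs
    ``gap_open + (L - 1) * gap_extend`` (both negative)."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("need match > 0 and mismatch < 0")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGTN symbol {exc}") from exc


@njit(cache=True)
def _sw_fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = a.size, b.size
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    best = 0
    bi, bj = 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = E[i, j - 1] + gap_extend
            eh = H[i, j - 1] + gap_open
            if eh > e:
                e = eh
            E[i, j] = e
            f = F[i - 1, j] + gap_extend
            fh = H[i - 1, j] + gap_open
            if fh > f:
                f = fh
            F[i, j] = f
            if a[i - 1] == b[j - 1] and a[i - 1] != 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi, bj = i, j
    return H, E, F, best, bi, bj


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of a pair: score, 1-based inclusive intervals on
    query and subject, alignment length in columns, and fractional identity."""

    score: int
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    length: int
    identity: float

    @property
    def is_hit(self) -> bool:
        return self.score > 0


_EMPTY = LocalAlignment(0, (0, 0), (0, 0), 0, 0.0)


def _traceback(a, b, scoring: Scoring, H, E, F, bi, bj) -> LocalAlignment:
    i, j = bi, bj
    state = "H"
    cols = 0
    matches = 0
    end_i, end_j = i, j
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            s = scoring.match if (a[i - 1] == b[j - 1] and a[i - 1] != 4) else scoring.mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                cols += 1
                if a[i - 1] == b[j - 1] and a[i - 1] != 4:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in query: consume subject symbol
            cols += 1
            if E[i, j] == H[i, j - 1] + scoring.gap_open:
                state = "H"
                j -= 1
            else:
                j -= 1
        else:  # gap in subject: consume query symbol
            cols += 1
            if F[i, j] == H[i - 1, j] + scoring.gap_open:
                state = "H"
                i -= 1
            else:
                i -= 1
    return LocalAlignment(
        score=int(H[bi, bj]),
        query_interval=(i + 1, end_i),
        subject_interval=(j + 1, end_j),
        length=cols,
        identity=matches / cols if cols else 0.0,
    )


def shared_words(seq1: str, seq2: str, word_size: int) -> bool:
    """True iff the sequences share an exact (N-free) word of ``word_size``."""
    if len(seq1) < word_size or len(seq2) < word_size:
        return False
    words = {
        seq1[i : i + word_size]
        for i in range(len(seq1) - word_size + 1)
        if "N" not in seq1[i : i + word_size]
    }
    return any(
        seq2[i : i + word_size] in words
        for i in range(len(seq2) - word_size + 1)
        if "N" not in seq2[i : i + word_size]
    )


def local_align(
    seq1: str,
    seq2: str,
    scoring: Scoring = Scoring(),
    mode: str = "seeded",
    word_size: int = 10,
) -> LocalAlignment:
    """Optimal local alignment under the given scheme.

    ``mode='exhaustive'`` always runs the full dynamic program;
    ``mode='seeded'`` first requires an exact shared ``word_size``-mer and
    reports no hit otherwise.
    """
    if mode not in ("seeded", "exhaustive"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    if not seq1 or not seq2:
        return _EMPTY
    if mode == "seeded" and not shared_words(seq1, seq2, word_size):
        return _EMPTY
    a, b = encode(seq1), encode(seq2)
    H, E, F, best, bi, bj = _sw_fill(
        a, b, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if best <= 0:
        return _EMPTY
    return _traceback(a, b, scoring, H, E, F, bi, bj)


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics (ungapped)


@lru_cache(maxsize=None)
def karlin_altschul_params(
    match: int, mismatch: int, p_match: float = 0.25
) -> tuple[float, float, float]:
    """(lambda, K, H) for an ungapped match/mismatch scheme under i.i.d.
    uniform base composition.

    lambda is the positive root of E[exp(lambda * X)] = 1 for the per-site
    score X; K follows the Karlin-Dembo renewal series evaluated by exact
    lattice convolution.  Reproduces the published ungapped blastn constants
    (e.g. +1/-2 -> lambda 1.333, K 0.621).
    """
    probs = {match: p_match, mismatch: 1.0 - p_match}
    if sum(s * p for s, p in probs.items()) >= 0:
        raise ValueError(
            "expected per-site score must be negative for E-value theory"
        )
    lam = brentq(
        lambda l: sum(p * math.exp(l * s) for s, p in probs.items()) - 1.0,
        1e-9,
        20.0,
    )
    tilted_mean = sum(s * p * math.exp(lam * s) for s, p in probs.items())
    entropy = lam * tilted_mean
    delta = math.gcd(abs(match), abs(mismatch))
    # sigma* = sum_k (1/k) [E(e^{lam S_k}; S_k < 0) + P(S_k >= 0)]
    walk = {0: 1.0}
    sigma = 0.0
    for k in range(1, 500):
        nxt: dict[int, float] = {}
        for s, ps in walk.items():
            for x, px in probs.items():
                nxt[s + x] = nxt.get(s + x, 0.0) + ps * px
        walk = nxt
        term = (
            sum(p * math.exp(lam * s) for s, p in walk.items() if s < 0)
            + sum(p for s, p in walk.items() if s >= 0)
        ) / k
        sigma += term
        if term < 1e-14:
            break
    K = delta * lam * math.exp(-2.0 * sigma) / (entropy * (1.0 - math.exp(-lam * delta)))
    return lam, K, entropy


def evalue(score: float, m: int, n: int, scoring: Scoring = Scoring()) -> float:
    """Ungapped Karlin-Altschul expect value E = K*m*n*exp(-lambda*S) for a
    local alignment score S between sequences of lengths m and n."""
    lam, K, _ = karlin_altschul_params(scoring.match, scoring.mismatch)
    return K * m * n * math.exp(-lam * score)
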