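"""Seed-anchored motif models from SELEX read pools.

Implements the multinomial counting scheme used for HT-SELEX motif
inference: an IUPAC seed anchors the counting, and base (or adjacent
dinucleotide) frequencies at each position are tallied from read windows
that match the seed everywhere *except* at the queried position (pair).
The mononucleotide counts yield a position weight matrix (PWM); the
dinucleotide counts yield a first-order Markov ("adjacent dinucleotide")
model that captures neighbour correlations a PWM cannot, such as the
AA/TT preference 5' of the E2F core site.

Only multinomial setting 1 (one mismatch tolerated, at the queried
position itself) is supported.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._alphabet import BASES, encode, iupac_matrix, revcomp_codes
from .pool import ReadPool

DINUC_LABELS = [a + b for a in BASES for b in BASES]


# --------------------------------------------------------------------- types

@dataclass(frozen=True)
class SeedPattern:
    """A degenerate IUPAC consensus used to anchor multinomial counting."""

    symbols: str

    def __post_init__(self):
        if len(self.symbols) < 2:
            raise ValueError("seed must have length >= 2")
        object.__setattr__(self, "symbols", self.symbols.upper())
        iupac_matrix(self.symbols)  # validates symbols

    def __len__(self) -> int:
        return len(self.symbols)

    def match_matrix(self) -> np.ndarray:
        return iupac_matrix(self.symbols)


@dataclass
class CountMatrix:
    """Observed multinomial counts for a seed of length L.

    ``mono_counts`` is (L, 4) over A,C,G,T; ``dinuc_counts`` is (L-1, 16)
    over AA..TT in row-major base order.
    """

    mono_counts: np.ndarray
    dinuc_counts: np.ndarray
    n_reads_scanned: int
    strands_counted: str = "both"
    n_reads_skipped: int = 0
    seed: Optional[SeedPattern] = None

    def __post_init__(self):
        self.mono_counts = np.asarray(self.mono_counts, dtype=np.int64)
        self.dinuc_counts = np.asarray(self.dinuc_counts, dtype=np.int64)
        L = self.mono_counts.shape[0]
        if self.mono_counts.shape != (L, 4):
            raise ValueError("mono_counts must be (L, 4)")
        if self.dinuc_counts.shape != (L - 1, 16):
            raise ValueError("dinuc_counts must be (L-1, 16)")
        if (self.mono_counts < 0).any() or (self.dinuc_counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def length(self) -> int:
        return self.mono_counts.shape[0]


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities (L, 4)."""

    probs: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (L, 4)")
        if (self.probs < -1e-12).any() or (self.probs > 1 + 1e-12).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def log_odds(self, background: Optional[np.ndarray] = None) -> np.ndarray:
        """(L, 4) log2 odds matrix; zero-probability cells map to -inf."""
        bg = _check_background(background)
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(bg)[None, :]

    # ----------------------------------------------------------------- I/O

    def to_tsv(self, path) -> None:
        _write_matrix_tsv(path, self.probs, BASES)

    @classmethod
    def from_tsv(cls, path) -> "PWM":
        return cls(_read_matrix_tsv(path, 4))

    def to_jaspar(self, path, name: str = "motif", counts_scale: int = 10000) -> None:
        """Write a JASPAR-style count block (probabilities x scale)."""
        counts = np.rint(self.probs * counts_scale).astype(int)
        with open(path, "w") as fh:
            fh.write(f">{name}\n")
            for bi, b in enumerate(BASES):
                row = " ".join(str(c) for c in counts[:, bi])
                fh.write(f"{b}  [ {row} ]\n")


@dataclass
class DinucModel:
    """Adjacent-dinucleotide (first-order Markov) model: (L-1, 16) rows of
    joint probabilities p_i(b1, b2) for neighbouring positions (i, i+1)."""

    pair_probs: np.ndarray

    def __post_init__(self):
        self.pair_probs = np.asarray(self.pair_probs, dtype=float)
        if self.pair_probs.ndim != 2 or self.pair_probs.shape[1] != 16:
            raise ValueError("pair_probs must be (L-1, 16)")
        if (self.pair_probs < -1e-12).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.pair_probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each pair row must sum to 1")

    def __len__(self) -> int:
        return self.pair_probs.shape[0] + 1

    def pair(self, i: int) -> np.ndarray:
        """Joint probabilities of pair (i, i+1) as a (4, 4) matrix."""
        return self.pair_probs[i].reshape(4, 4)

    # ----------------------------------------------------------------- I/O

    def to_tsv(self, path) -> None:
        _write_matrix_tsv(path, self.pair_probs, DINUC_LABELS)

    @classmethod
    def from_tsv(cls, path) -> "DinucModel":
        return cls(_read_matrix_tsv(path, 16))


def _check_background(background: Optional[np.ndarray]) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or (bg <= 0).any():
        raise ValueError("background must be a positive 4-vector summing to 1")
    return bg


def _write_matrix_tsv(path, matrix, labels) -> None:
    with open(path, "w") as fh:
        fh.write("pos\t" + "\t".join(labels) + "\n")
        for i, row in enumerate(matrix):
            fh.write(str(i) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def _read_matrix_tsv(path, ncols) -> np.ndarray:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("pos"):
            raise ValueError(f"{path}: expected a 'pos\\t...' header line")
        for line in fh:
            parts = line.split()
            if parts:
                rows.append([float(v) for v in parts[1 : ncols + 1]])
    return np.asarray(rows)


# ------------------------------------------------------------------ counting

def count_multinomial(
    pool: ReadPool | Sequence[str],
    seed: SeedPattern | str,
    setting: int = 1,
    strands: str = "both",
) -> CountMatrix:
    """Tally seed-anchored multinomial counts over every read window.

    For mononucleotide counts at seed position ``i`` a window contributes
    when it matches the seed (IUPAC-wise) at all positions except ``i``;
    the base observed at ``i`` is tallied whatever it is.  Dinucleotide
    counts at pair ``(i, i+1)`` analogously require a match everywhere
    except at the two paired positions.  With ``strands='both'`` the
    reverse complement of every read is scanned as well.

    Reads containing non-ACGT characters are skipped and reported in
    ``n_reads_skipped``.
    """
    if setting != 1:
        raise ValueError("only multinomial setting=1 is supported")
    if strands not in ("forward", "both"):
        raise ValueError("strands must be 'forward' or 'both'")
    if not isinstance(seed, SeedPattern):
        seed = SeedPattern(seed)
    if not isinstance(pool, ReadPool):
        pool = ReadPool(list(pool))
    if len(pool) == 0:
        raise ValueError("empty read pool")

    L = len(seed)
    codes = pool.codes()
    if codes.shape[1] < L:
        raise ValueError("seed longer than the reads")
    valid = (codes >= 0).all(axis=1)
    codes = codes[valid]
    n_skipped = int((~valid).sum())
    if codes.shape[0] == 0:
        raise ValueError("no valid reads after skipping non-ACGT reads")

    allowed = seed.match_matrix()
    mono = np.zeros((L, 4), dtype=np.int64)
    dinuc = np.zeros((L - 1, 16), dtype=np.int64)

    strand_mats = [codes]
    if strands == "both":
        strand_mats.append(revcomp_codes(codes))

    pos_idx = np.arange(L)
    for mat in strand_mats:
        windows = sliding_window_view(mat, L, axis=1)        # (n, W, L)
        ok = allowed[pos_idx[None, None, :], windows]        # (n, W, L) bool
        nmatch = ok.sum(axis=2)
        for i in range(L):
            sel = (nmatch - ok[:, :, i]) == L - 1
            if sel.any():
                mono[i] += np.bincount(windows[:, :, i][sel], minlength=4)
        for i in range(L - 1):
            sel = (nmatch - ok[:, :, i] - ok[:, :, i + 1]) == L - 2
            if sel.any():
                pair_codes = windows[:, :, i][sel] * 4 + windows[:, :, i + 1][sel]
                dinuc[i] += np.bincount(pair_codes, minlength=16)

    return CountMatrix(mono, dinuc, n_reads_scanned=int(codes.shape[0]),
                       strands_counted=strands, n_reads_skipped=n_skipped,
                       seed=seed)


def pwm_from_counts(counts: CountMatrix, pseudocount: float = 1.0) -> PWM:
    """Normalize mononucleotide counts into a PWM.

    p_i(b) = (count + pseudocount) / (row total + 4 * pseudocount).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    c = counts.mono_counts.astype(float) + pseudocount
    totals = c.sum(axis=1)
    if (totals == 0).any():
        bad = int(np.flatnonzero(totals == 0)[0])
        raise ValueError(f"all-zero counts at position {bad} with pseudocount=0")
    return PWM(c / totals[:, None], pseudocount=pseudocount)


def dinuc_model_from_counts(counts: CountMatrix, pseudocount: float = 1.0) -> DinucModel:
    """Normalize adjacent-dinucleotide counts into a first-order model."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    c = counts.dinuc_counts.astype(float) + pseudocount
    totals = c.sum(axis=1)
    if (totals == 0).any():
        bad = int(np.flatnonzero(totals == 0)[0])
        raise ValueError(f"all-zero counts at pair {bad} with pseudocount=0")
    return DinucModel(c / totals[:, None])


# ----------------------------------------------------------------- consensus

@dataclass(frozen=True)
class Consensus:
    """Per-position argmax string; tie positions broken A<C<G<T and flagged."""

    sequence: str
    tie_positions: Tuple[int, ...] = ()

    def __str__(self) -> str:
        return self.sequence

    def __contains__(self, item: str) -> bool:
        return item in self.sequence


def consensus(pwm: PWM, tie_tol: float = 1e-12) -> Consensus:
    best = pwm.probs.argmax(axis=1)  # argmax takes the lowest index on ties
    maxp = pwm.probs.max(axis=1)
    ties = tuple(
        int(i) for i in range(len(pwm))
        if (np.abs(pwm.probs[i] - maxp[i]) <= tie_tol).sum() > 1
    )
    return Consensus("".join(BASES[b] for b in best), ties)


# ------------------------------------------------------------------- scoring

def log_odds_score(window: str | np.ndarray, pwm: PWM,
                   background: Optional[np.ndarray] = None) -> float:
    """Sum of per-position log2(p_i(b_i)/bg(b_i)); -inf for non-ACGT."""
    codes = encode(window) if isinstance(window, str) else np.asarray(window)
    if codes.shape[0] != len(pwm):
        raise ValueError("window length must equal the PWM length")
    if (codes < 0).any():
        return float("-inf")
    lo = pwm.log_odds(background)
    return float(lo[np.arange(len(pwm)), codes].sum())


@dataclass(frozen=True)
class ScanHit:
    position: int
    strand: str  # '+' or '-'
    score: float


def scan(seq: str | np.ndarray, pwm: PWM, both_strands: bool = True,
         background: Optional[np.ndarray] = None) -> ScanHit:
    """Best-scoring window over a sequence.

    Ties resolve to the lowest position, forward strand first.  The minus-
    strand position refers to the forward-strand coordinate of the window.
    """
    codes = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.int8)
    L = len(pwm)
    if codes.shape[0] < L:
        raise ValueError("sequence shorter than the PWM")
    scores = _window_scores(codes[None, :], pwm.log_odds(background))[0]
    best_pos = int(np.argmax(scores))
    best = ScanHit(best_pos, "+", float(scores[best_pos]))
    if both_strands:
        rc_scores = _window_scores(revcomp_codes(codes[None, :]), pwm.log_odds(background))[0]
        # window at RC index j corresponds to forward position W-1-j
        rc_scores = rc_scores[::-1]
        pos = int(np.argmax(rc_scores))
        if rc_scores[pos] > best.score:
            best = ScanHit(pos, "-", float(rc_scores[pos]))
    return best


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """(n, W) matrix of window scores; windows with invalid bases -> -inf.

    Accumulates per-seed-position contributions over shifted slices,
    which is much faster than materializing an (n, W, L) window tensor.
    """
    L = log_odds.shape[0]
    n, Lr = codes.shape
    W = Lr - L + 1
    bad = codes < 0
    safe = np.where(bad, 0, codes)
    scores = np.zeros((n, W), dtype=np.float64)
    invalid = np.zeros((n, W), dtype=bool)
    for i in range(L):
        scores += log_odds[i, safe[:, i:i + W]]
        invalid |= bad[:, i:i + W]
    scores[invalid] = -np.inf
    return scores


def best_window_scores(codes: np.ndarray, pwm_or_dinuc, both_strands: bool = True,
                       background: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-read best-window log2-odds over one or both strands.

    Accepts a PWM or a DinucModel; the Markov score of a window under a
    DinucModel is log2 m_0(b_0)/bg(b_0) + sum_i log2 P_i(b_{i+1}|b_i)/bg(b_{i+1}),
    i.e. the log likelihood ratio of the window's joint probability.
    """
    from .riverlake import mono_from_dinuc  # local import, no cycle at runtime

    bg = _check_background(background)
    if isinstance(pwm_or_dinuc, PWM):
        scores = _window_scores(codes, pwm_or_dinuc.log_odds(bg))
        if both_strands:
            rc = _window_scores(revcomp_codes(codes), pwm_or_dinuc.log_odds(bg))
            scores = np.maximum(scores, rc[:, ::-1])
        return scores.max(axis=1)

    model: DinucModel = pwm_or_dinuc
    L = len(model)
    mono = mono_from_dinuc(model)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = model.pair_probs.reshape(-1, 4, 4) / np.where(
            mono[:-1][:, :, None] > 0, mono[:-1][:, :, None], np.nan)
        lo_pairs = np.log2(cond) - np.log2(bg)[None, None, :]
        lo_first = np.log2(mono[0]) - np.log2(bg)
    lo_pairs = np.nan_to_num(lo_pairs, nan=-np.inf, neginf=-np.inf)

    def markov_scores(mat):
        n, Lr = mat.shape
        W = Lr - L + 1
        bad = mat < 0
        safe = np.where(bad, 0, mat)
        s = lo_first[safe[:, 0:W]].astype(np.float64)
        invalid = bad[:, 0:W].copy()
        for i in range(L - 1):
            s += lo_pairs[i, safe[:, i:i + W], safe[:, i + 1:i + 1 + W]]
            invalid |= bad[:, i + 1:i + 1 + W]
        s[invalid] = -np.inf
        return s

    scores = markov_scores(codes)
    if both_strands:
        scores = np.maximum(scores, markov_scores(revcomp_codes(codes))[:, ::-1])
    return scores.max(axis=1)


# --------------------------------------------------- Model/Results interface

class MultinomialMotifModel:
    """Seed-anchored motif model of one SELEX cycle, statsmodels-style.

    >>> res = MultinomialMotifModel(pool, "NTTTGGCGGGAAAN").fit()
    >>> res.pwm, res.dinuc_model, str(res.consensus)
    """

    def __init__(self, pool: ReadPool, seed: SeedPattern | str,
                 strands: str = "both"):
        self.pool = pool
        self.seed = seed if isinstance(seed, SeedPattern) else SeedPattern(seed)
        self.strands = strands

    def fit(self, pseudocount: float = 1.0) -> "MotifResults":
        counts = count_multinomial(self.pool, self.seed, strands=self.strands)
        return MotifResults(
            model=self,
            counts=counts,
            pwm=pwm_from_counts(counts, pseudocount),
            dinuc_model=dinuc_model_from_counts(counts, pseudocount),
            pseudocount=pseudocount,
        )


@dataclass
class MotifResults:
    model: MultinomialMotifModel
    counts: CountMatrix
    pwm: PWM
    dinuc_model: DinucModel
    pseudocount: float
    _consensus: Consensus = field(default=None, repr=False)

    @property
    def consensus(self) -> Consensus:
        if self._consensus is None:
            self._consensus = consensus(self.pwm)
        return self._consensus

    def summary(self) -> str:
        lines = [
            "Multinomial (setting=1) motif model",
            f"  seed:            {self.model.seed.symbols}",
            f"  strands counted: {self.counts.strands_counted}",
            f"  reads scanned:   {self.counts.n_reads_scanned}"
            f" (skipped {self.counts.n_reads_skipped})",
            f"  pseudocount:     {self.pseudocount:g}",
            f"  consensus:       {self.consensus.sequence}"
            + (f"  (ties at {list(self.consensus.tie_positions)})"
               if self.consensus.tie_positions else ""),
            "",
            "  pos      A      C      G      T",
        ]
        for i, row in enumerate(self.pwm.probs):
            lines.append("  %3d  %5.3f  %5.3f  %5.3f  %5.3f" % (i, *row))
        return "\n".join(lines)
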