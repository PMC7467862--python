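"""Runs-of-identity haplotypes over the orthologous SNP matrix.

Pairwise detection follows the seed-and-extend recipe: windows of at least
``seed_min`` (default 40) consecutive identical SNP calls act as seeds —
far above the null expectation for unrelated lines, which randomization
(run-of-heads) statistics place in the low tens — and are extended into
maximal segments that keep at least ``min_identity`` (default 98%)
identical calls.  The segment finder is exact: it enumerates *all* maximal
segments satisfying (contains a seed window) AND (identity >= threshold),
using integer prefix-score records rather than a stepwise greedy walk.

Reported runs merge overlapping maximal segments and, by default, trim the
reported extent to the outermost seed windows: the sub-threshold extension
tails that maximal segments necessarily carry (expected length
(q - t)/(t - p) x m sites per side for in-run identity q, threshold t,
background identity p and m run sites) are noise with respect to the
underlying shared haplotype and would inflate genomic spans by several
percent.  ``trim_to_seeds=False`` reports the raw maximal extents.

Higher-order haplotypes re-express each site as the 15-bit vector of
pairwise run membership and find maximal stretches of constant nonzero
pattern, bridging up to ``bridge_max_mismatch`` (default 2) nonmatching
sites between same-pattern stretches.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "NullRunStats", "PairwiseRun", "HigherOrderHaplotype",
    "max_run_null", "enumerate_identity_segments", "find_pairwise_runs",
    "pair_order", "binarize", "find_higher_order", "summarize_spans",
]


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

@dataclass
class NullRunStats:
    """Empirical and asymptotic maximal run-of-heads statistics."""

    n_sites: int
    identity_prob: float
    n_reps: int
    rng_seed: int
    max_run_distribution: np.ndarray
    expected_max: float
    asymptotic_max: float

    def seed_rate(self, seed_min: int = 40) -> float:
        """Fraction of replicates whose maximal run reaches ``seed_min``."""
        return float(np.mean(self.max_run_distribution >= seed_min))


def _max_true_run(v: np.ndarray) -> int:
    """Length of the longest run of True values."""
    if not v.any():
        return 0
    w = np.concatenate([[False], v, [False]])
    d = np.diff(w.astype(np.int8))
    return int((np.flatnonzero(d == -1) - np.flatnonzero(d == 1)).max())


def max_run_null(n_sites: int, p: float, n_reps: int = 500,
                 seed: int = 0) -> NullRunStats:
    """Monte-Carlo distribution of the maximal run of identical SNP calls
    between two unrelated lines, alongside the Erdos–Renyi asymptotic
    ``log_{1/p}(n (1-p))``."""
    if n_sites < 1:
        raise InputError("n_sites must be >= 1")
    if not 0.0 < p < 1.0:
        raise InputError("identity probability must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_reps, dtype=np.int64)
    for r in range(n_reps):
        maxima[r] = _max_true_run(rng.random(n_sites) < p)
    asymptotic = float(np.log(n_sites * (1.0 - p)) / np.log(1.0 / p))
    return NullRunStats(n_sites, p, n_reps, seed, maxima,
                        float(maxima.mean()), asymptotic)


# ---------------------------------------------------------------------------
# Exact maximal-segment enumeration
# ---------------------------------------------------------------------------

def _true_runs(match: np.ndarray):
    w = np.concatenate([[False], match, [False]])
    d = np.diff(w.astype(np.int8))
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1)


def enumerate_identity_segments(match, seed_min: int = 40,
                                min_identity: float = 0.98):
    """All maximal site-index segments [i, j) that (a) contain at least
    ``seed_min`` consecutive identical sites and (b) have an identical-call
    fraction >= ``min_identity``.

    Identity comparisons use exact integer arithmetic on the rational
    threshold.  Maximal means not contained in any other segment that also
    satisfies (a) and (b).
    """
    match = np.asarray(match, dtype=bool)
    n = match.size
    if n == 0:
        return []
    rs, re = _true_runs(match)
    keep = (re - rs) >= seed_min
    rs, re = rs[keep], re[keep]
    if rs.size == 0:
        return []
    frac = Fraction(min_identity).limit_denominator(10 ** 6)
    num, den = frac.numerator, frac.denominator
    P = np.concatenate([[0], np.cumsum(match, dtype=np.int64)])
    Q = den * P - num * np.arange(n + 1, dtype=np.int64)
    i_max = int((re - seed_min).max())          # last admissible left end
    j_min = int((rs + seed_min).min())          # first admissible right end
    # left-end candidates: strict prefix minima of Q over [0, i_max]
    pm = np.minimum.accumulate(Q[:i_max + 1])
    rec_i = np.flatnonzero(np.concatenate([[True], pm[1:] < pm[:-1]]))
    # right-end candidates: suffix maxima of Q over [j_min, n] (rightmost of
    # equal values)
    Qj = Q[j_min:]
    sm = np.maximum.accumulate(Qj[::-1])[::-1]
    is_rec = Qj == sm
    if is_rec.size > 1:
        is_rec[:-1] &= Qj[:-1] > sm[1:]
    rec_j = np.flatnonzero(is_rec) + j_min
    recQ_neg = -Q[rec_j]                        # increasing

    def f_of(i: int) -> int:
        """Minimal right end j such that [i, j) contains a full seed."""
        best = n + 1
        k = int(np.searchsorted(rs, i, side="left"))
        if k < rs.size:
            best = int(rs[k]) + seed_min
        if k > 0 and re[k - 1] >= i + seed_min:
            best = min(best, i + seed_min)
        return best

    out = []
    best_j = -1
    for i in rec_i:
        t = int(np.searchsorted(recQ_neg, -Q[i], side="right")) - 1
        if t < 0:
            continue
        j = int(rec_j[t])
        if j < f_of(int(i)):
            continue
        if j > best_j:
            out.append((int(i), j))
            best_j = j
    return out


# ---------------------------------------------------------------------------
# Pairwise runs
# ---------------------------------------------------------------------------

@dataclass
class PairwiseRun:
    """One run-of-identity haplotype between two lines.

    ``start``/``end`` index sites of the SnpMatrix (half-open, within one
    core block); ``spans`` gives the genomic extent per line.
    """

    pair: tuple[str, str]
    block_id: int
    start: int
    end: int
    n_sites: int
    n_identical: int
    identity: float
    spans: dict[str, tuple[str, int, int]]


def _block_slices(block_ids: np.ndarray):
    if block_ids.size == 0:
        return
    edges = np.flatnonzero(np.diff(block_ids)) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [block_ids.size]])
    for s, e in zip(starts, ends):
        yield int(block_ids[s]), int(s), int(e)


def _span_of(matrix, line: str, s: int, e: int):
    li = matrix.line_index(line)
    pos = matrix.positions[s:e, li]
    return (str(matrix.chroms[s]), int(pos.min()), int(pos.max()) + 1)


def find_pairwise_runs(matrix, pair: tuple[str, str], seed_min: int = 40,
                       min_identity: float = 0.98, merge: bool = True,
                       trim_to_seeds: bool = True) -> list[PairwiseRun]:
    """Detect runs-of-identity for one line pair.

    Segments are enumerated exactly per core block (runs never cross block
    or chromosome boundaries), overlapping maximal segments are merged, and
    the reported extent is trimmed to the outermost seed windows unless
    ``trim_to_seeds=False``.  ``merge=False, trim_to_seeds=False`` returns
    the raw maximal segments.
    """
    for ln in pair:
        if ln not in matrix.lines:
            raise InputError(f"unknown line {ln!r} in pair")
    match_all = matrix.pair_match(*pair)
    runs: list[PairwiseRun] = []
    for bid, bs, be in _block_slices(matrix.block_ids):
        match = match_all[bs:be]
        segs = enumerate_identity_segments(match, seed_min, min_identity)
        if not segs:
            continue
        if merge:
            groups = []
            cur_s, cur_e = segs[0]
            for s, e in segs[1:]:
                if s < cur_e:
                    cur_e = max(cur_e, e)
                else:
                    groups.append((cur_s, cur_e))
                    cur_s, cur_e = s, e
            groups.append((cur_s, cur_e))
        else:
            groups = segs
        rs, re = _true_runs(match)
        keep = (re - rs) >= seed_min
        rs, re = rs[keep], re[keep]
        P = np.concatenate([[0], np.cumsum(match, dtype=np.int64)])
        for s, e in groups:
            if trim_to_seeds:
                lo, hi = None, None
                for a, b in zip(rs, re):
                    ov_s, ov_e = max(s, int(a)), min(e, int(b))
                    if ov_e - ov_s >= seed_min:
                        lo = ov_s if lo is None else min(lo, ov_s)
                        hi = ov_e if hi is None else max(hi, ov_e)
                if lo is None:
                    continue
                s, e = lo, hi
            ident = int(P[e] - P[s])
            runs.append(PairwiseRun(
                pair=tuple(pair), block_id=bid, start=bs + s, end=bs + e,
                n_sites=e - s, n_identical=ident,
                identity=ident / (e - s) if e > s else 1.0,
                spans={ln: _span_of(matrix, ln, bs + s, bs + e)
                       for ln in pair}))
    return runs


# ---------------------------------------------------------------------------
# Higher-order haplotypes
# ---------------------------------------------------------------------------

def pair_order(lines) -> list[tuple[str, str]]:
    """Fixed ordering of the line pairs (lexicographic combinations)."""
    return list(itertools.combinations(list(lines), 2))


def binarize(matrix, runs_by_pair: dict[tuple[str, str], list[PairwiseRun]]
             ) -> np.ndarray:
    """Per-site bit-vectors over the pair order: bit (i, j) is set iff the
    site lies inside a reported run of pair (i, j)."""
    pairs = pair_order(matrix.lines)
    bits = np.zeros((matrix.n_sites, len(pairs)), dtype=bool)
    index = {p: k for k, p in enumerate(pairs)}
    for p, runs in runs_by_pair.items():
        k = index.get(tuple(p), index.get(tuple(reversed(p))))
        if k is None:
            raise InputError(f"pair {p} not in pair order")
        for r in runs:
            bits[r.start:r.end, k] = True
    return bits


@dataclass
class HigherOrderHaplotype:
    """Maximal stretch of constant nonzero pairwise-run pattern."""

    pattern: tuple[int, ...]
    block_id: int
    start: int
    end: int
    n_sites: int                 # matching sites only (bridges excluded)
    spans: dict[str, tuple[str, int, int]]

    @property
    def bitstring(self) -> str:
        return "".join(str(b) for b in self.pattern)


def find_higher_order(bits: np.ndarray, matrix, seed_min: int = 40,
                      bridge_max_mismatch: int = 2) -> list[HigherOrderHaplotype]:
    """Derive higher-order haplotypes from per-site pair-membership bits.

    Within each block, maximal stretches of a constant nonzero pattern act
    as runs; same-pattern runs separated by at most ``bridge_max_mismatch``
    nonmatching sites are linked, and a linked group is reported when it
    contains a run of at least ``seed_min`` consecutive sites.
    """
    weights = (1 << np.arange(bits.shape[1], dtype=np.int64))
    packed = bits @ weights
    out: list[HigherOrderHaplotype] = []
    for bid, bs, be in _block_slices(matrix.block_ids):
        codes = packed[bs:be]
        if codes.size == 0:
            continue
        edges = np.flatnonzero(np.diff(codes)) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [codes.size]])
        by_pattern: dict[int, list[tuple[int, int]]] = {}
        for s, e in zip(starts, ends):
            c = int(codes[s])
            if c != 0:
                by_pattern.setdefault(c, []).append((int(s), int(e)))
        for code, segs in by_pattern.items():
            groups: list[list[tuple[int, int]]] = [[segs[0]]]
            for s, e in segs[1:]:
                if s - groups[-1][-1][1] <= bridge_max_mismatch:
                    groups[-1].append((s, e))
                else:
                    groups.append([(s, e)])
            pattern = tuple(int(b) for b in
                            (code >> np.arange(bits.shape[1])) & 1)
            for grp in groups:
                if max(e - s for s, e in grp) < seed_min:
                    continue
                s0, e0 = grp[0][0], grp[-1][1]
                out.append(HigherOrderHaplotype(
                    pattern=pattern, block_id=bid, start=bs + s0, end=bs + e0,
                    n_sites=sum(e - s for s, e in grp),
                    spans={ln: _span_of(matrix, ln, bs + s0, bs + e0)
                           for ln in matrix.lines}))
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_spans(items) -> pd.DataFrame:
    """Count / mean span / total span per pair (PairwiseRun input) or per
    15-bit pattern (HigherOrderHaplotype input), sorted by total span.

    The span of one run is the mean of its per-line genomic extents.
    """
    rows = []
    if items and isinstance(items[0], HigherOrderHaplotype):
        keyname = "pattern"
        keyed = {}
        for h in items:
            keyed.setdefault(h.bitstring, []).append(h)
    else:
        keyname = "pair"
        keyed = {}
        for r in items:
            keyed.setdefault("|".join(r.pair), []).append(r)
    for key, group in keyed.items():
        spans = [float(np.mean([e - s for (_, s, e) in it.spans.values()]))
                 for it in group]
        rows.append({keyname: key, "count": len(group),
                     "n_sites": int(sum(it.n_sites for it in group)),
                     "mean_span_bp": float(np.mean(spans)),
                     "total_span_bp": float(np.sum(spans))})
    if not rows:
        return pd.DataFrame(columns=[keyname, "count", "n_sites",
                                     "mean_span_bp", "total_span_bp"])
    df = pd.DataFrame(rows).sort_values("total_span_bp", ascending=False)
    return df.reset_index(drop=True)
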