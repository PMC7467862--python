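"""Independent oracles and measurement helpers shared across tests."""

from __future__ import annotations

from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# Brute-force maximal-segment oracle (independent of the package's
# record-based enumerator: seed windows by convolution, validity by direct
# integer identity comparison per candidate right end, Pareto by scan).
# ---------------------------------------------------------------------------

def brute_segments(match, seed_min, min_identity):
    match = np.asarray(match, dtype=bool)
    n = match.size
    if n == 0:
        return []
    P = np.concatenate([[0], np.cumsum(match, dtype=np.int64)])
    fr = Fraction(min_identity).limit_denominator(10 ** 6)
    num, den = fr.numerator, fr.denominator
    full = np.convolve(match.astype(int), np.ones(seed_min, dtype=int),
                       "valid") == seed_min
    if not full.any():
        return []
    wstart = set(np.flatnonzero(full).tolist())
    f = np.full(n + 2, n + 5, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        f[i] = f[i + 1]
        if i in wstart:
            f[i] = min(f[i], i + seed_min)
    res = []
    best = -1
    for i in range(n):
        if f[i] > n:
            continue
        js = np.arange(f[i], n + 1)
        valid = (P[js] - P[i]) * den >= num * (js - i)
        if not valid.any():
            continue
        J = int(js[valid].max())
        if J > best:
            res.append((i, J))
            best = J
    return res


# ---------------------------------------------------------------------------
# Brute-force priority overlap resolution (per-base boolean arrays).
# ---------------------------------------------------------------------------

def brute_resolve(hits, shorten_cov=0.90, min_rest=50, span=10 ** 6):
    """Returns the resolved intervals as a set of (chrom, start, end,
    element) tuples, evaluating the greedy rule with per-base masks."""
    order = sorted(hits, key=lambda h: (-h.score, h.chrom, h.start, h.end,
                                        h.element, h.strand))
    taken = {}
    out = set()
    for h in order:
        mask = taken.setdefault(h.chrom, np.zeros(span, dtype=bool))
        seg = mask[h.start:h.end]
        cov = int(seg.sum())
        length = h.end - h.start
        if cov == 0:
            pieces = [(h.start, h.end)]
        elif cov >= shorten_cov * length:
            continue
        else:
            free = ~seg
            d = np.diff(np.concatenate([[0], free.astype(np.int8), [0]]))
            ss = np.flatnonzero(d == 1)
            ee = np.flatnonzero(d == -1)
            pieces = [(h.start + int(a), h.start + int(b))
                      for a, b in zip(ss, ee)]
            if any(b - a < min_rest for a, b in pieces):
                continue
        for a, b in pieces:
            out.add((h.chrom, a, b, h.element))
            mask[a:b] = True
    return out


# ---------------------------------------------------------------------------
# Measurement helpers over a PanelAnalysis + TruthSet
# ---------------------------------------------------------------------------

def base_jaccard(truth_ivs, detected_ivs):
    """Base-level Jaccard of two interval collections [(chrom, s, e), ...]."""
    inter = union = 0
    T, D = {}, {}
    for c, s, e in truth_ivs:
        T.setdefault(c, []).append((s, e))
    for c, s, e in detected_ivs:
        D.setdefault(c, []).append((s, e))
    for c in set(T) | set(D):
        hi = max(e for _, e in T.get(c, []) + D.get(c, [])) + 1
        mt = np.zeros(hi, dtype=bool)
        md = np.zeros(hi, dtype=bool)
        for s, e in T.get(c, []):
            mt[s:e] = True
        for s, e in D.get(c, []):
            md[s:e] = True
        inter += int((mt & md).sum())
        union += int((mt | md).sum())
    return inter / union if union else 1.0


def ibd_jaccard(analysis):
    """Aggregate base-level Jaccard of detected pairwise runs vs planted
    IBD tracts over all line pairs."""
    from panmosaic.haplotypes import pair_order
    truth = analysis.truth
    runs = analysis.pairwise_runs
    m = analysis.snp_matrix
    inter = union = 0
    for pair in pair_order(m.lines):
        a, b = pair
        tr = []
        for ev in truth.ibd_events.itertuples():
            subset = ev.subset.split(",")
            if a in subset and b in subset:
                row = truth.ibd_loci[(truth.ibd_loci.tract_id == ev.tract_id)
                                     & (truth.ibd_loci.line == a)]
                tr.append((row.chrom.iloc[0], int(row.start.iloc[0]),
                           int(row.end.iloc[0])))
        det = [r.spans[a] for r in runs[pair]]
        j = base_jaccard(tr, det)
        # accumulate in base units rather than averaging pair ratios
        T, D = {}, {}
        for c, s, e in tr:
            T.setdefault(c, []).append((s, e))
        for c, s, e in det:
            D.setdefault(c, []).append((s, e))
        for c in set(T) | set(D):
            hi = max(e for _, e in T.get(c, []) + D.get(c, [])) + 1
            mt = np.zeros(hi, dtype=bool)
            md = np.zeros(hi, dtype=bool)
            for s, e in T.get(c, []):
                mt[s:e] = True
            for s, e in D.get(c, []):
                md[s:e] = True
            inter += int((mt & md).sum())
            union += int((mt | md).sum())
    return inter / union if union else 1.0


def clade_pattern(analysis, clade=("fl1", "fl2", "fl3", "fl4")):
    """The 15-bit pattern with exactly the within-clade pair bits set."""
    from panmosaic.haplotypes import pair_order
    pairs = pair_order(analysis.snp_matrix.lines)
    return tuple(1 if set(p) <= set(clade) else 0 for p in pairs)


def label_fraction(analysis, loci, label):
    """Aggregate fraction of the given truth loci labelled ``label`` in the
    per-line partitions."""
    tot = hit = 0
    for r in loci.itertuples():
        iv = analysis.partitions[r.line].intervals
        sub = iv[(iv.chrom == r.chrom) & (iv.end > r.start)
                 & (iv.start < r.end) & (iv.label == label)]
        hit += sum(min(r.end, q.end) - max(r.start, q.start)
                   for q in sub.itertuples())
        tot += r.end - r.start
    return hit / tot if tot else float("nan")


def sharing_accuracy(analysis):
    """Fraction of planted (filter-passing) TE events whose detected sharing
    set equals the truth carrier set."""
    det = {}
    for rec in analysis.sharing_records:
        for eid in rec.element_ids:
            det[eid.split(":", 1)[1]] = rec.lines
    event_ids = {e.element_id.split(":", 1)[1] for e in analysis.ltr_elements}
    ok = sum(det.get(eid) == frozenset(analysis.truth.carriers_of_te(eid))
             for eid in event_ids)
    return ok / len(event_ids), len(event_ids)


def pav_accuracy(analysis):
    """Fraction of genes whose PAV label matches the planted carrier count."""
    from panmosaic.pangene import classify_pav
    labels, _ = classify_pav(analysis.gene_clusters, len(analysis.lines))
    truth_size = {r.origin_id: len(r.carriers.split(","))
                  for r in analysis.truth.gene_events.itertuples()}
    n = len(analysis.lines)
    ok = tot = 0
    for cl in analysis.gene_clusters:
        for line, gid in cl.members:
            t = truth_size[gid.split("_", 1)[1]]
            want = "core" if t == n else ("singleton" if t == 1 else "dispensable")
            tot += 1
            ok += labels[(line, gid)] == want
    return ok / tot, tot


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    from math import comb
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c) / denom
    p = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = comb(r1, x) * comb(r2, c1 - x) / denom
        if px <= p_obs * (1 + 1e-9):
            p += px
    return min(p, 1.0)
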