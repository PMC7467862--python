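"""Homology-based repeat annotation, priority overlap resolution, knob
satellite arrays and gene-neighbourhood statistics.

The scanner reports seeded, gaplessly-extended local matches against a
repeat library (identity >= 70%, length >= 75 bp, 12-bp exact seeds, both
strands).  Overlap resolution assigns higher-scoring hits first and either
shortens lower-scoring overlaps (when covered < 90% and every remainder
keeps >= 50 bp) or removes them, leaving a strictly overlap-free
annotation.  Knob arrays chain same-monomer hits separated by at most a
small gap; a single isolated monomer counts as a (cryptic) array of one
unit.
"""

from __future__ import annotations

from bisect import bisect_right, insort
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _seq
from .errors import InputError

__all__ = ["RepeatHit", "KnobArray", "NeighborhoodRecord", "homology_scan",
           "resolve_overlaps", "find_knob_arrays", "gene_neighborhood"]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class RepeatHit:
    chrom: str
    start: int
    end: int
    strand: str
    element: str                 # library element id
    element_class: str
    identity: float
    score: float
    hit_id: int = -1
    trimmed: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class KnobArray:
    chrom: str
    start: int
    end: int
    monomer: str                 # knob180 | tr1_202
    unit_count: int
    mean_identity: float


@dataclass
class NeighborhoodRecord:
    gene_id: str
    element_class: str
    upstream_distance: int | None      # None = no element on the contig
    max_tpm: float | None = None


# ---------------------------------------------------------------------------
# Homology scan
# ---------------------------------------------------------------------------

def _scan_one(chrom, garr, lib_name, lib_class, larr, strand, seed_len,
              min_identity, min_len):
    """Seeded diagonal scan of one library element against one chromosome
    strand; one candidate window per diagonal carrying a seed, trimmed to
    its best-scoring sub-segment (match +1 / mismatch -2)."""
    n, m = garr.size, larr.size
    if n < seed_len or m < seed_len:
        return []
    gcodes = _seq.kmer_codes(garr, seed_len)
    lcodes = _seq.kmer_codes(larr, seed_len)
    lorder = np.argsort(lcodes, kind="stable")
    lsorted = lcodes[lorder]
    idx = np.searchsorted(lsorted, gcodes)
    idx_clip = np.minimum(idx, lsorted.size - 1)
    has = lsorted[idx_clip] == gcodes
    gpos_all = np.flatnonzero(has)
    hits = []
    diag_seen: set[int] = set()
    for g in gpos_all:
        code = gcodes[g]
        lo = int(np.searchsorted(lsorted, code, side="left"))
        hi = int(np.searchsorted(lsorted, code, side="right"))
        for l in lorder[lo:hi]:
            diag = int(g) - int(l)
            if diag in diag_seen:
                continue
            diag_seen.add(diag)
            gs = max(0, diag)
            ge = min(n, diag + m)
            if ge - gs < min_len:
                continue
            sub_g = garr[gs:ge]
            sub_l = larr[gs - diag:ge - diag]
            match = sub_g == sub_l
            # best-scoring sub-segment (Kadane on +1/-2)
            scorevec = np.where(match, 1, -2).astype(np.int64)
            best, cur, cur_s, bs, be = 0, 0, 0, 0, 0
            for i2, v in enumerate(scorevec):
                cur += v
                if cur <= 0:
                    cur, cur_s = 0, i2 + 1
                elif cur > best:
                    best, bs, be = cur, cur_s, i2 + 1
            if be - bs < min_len:
                continue
            ident = float(match[bs:be].mean())
            if ident < min_identity:
                continue
            s_, e_ = gs + bs, gs + be
            if strand == "-":
                s_, e_ = n - e_, n - s_
            hits.append(RepeatHit(chrom, int(s_), int(e_), strand, lib_name,
                                  lib_class, ident,
                                  score=ident * (e_ - s_)))
    return hits


def homology_scan(genome: dict[str, object], library: dict[str, object],
                  min_identity: float = 0.70, min_len: int = 75,
                  seed_len: int = 12,
                  classes: dict[str, str] | None = None) -> list[RepeatHit]:
    """Scan a genome against a repeat library on both strands.

    ``library`` maps element names to sequences; ``classes`` optionally
    maps element names to annotation classes (defaults to the name).
    """
    if not library:
        raise InputError("repeat library must be nonempty")
    classes = classes or {}
    hits: list[RepeatHit] = []
    for chrom, seq in genome.items():
        garr = _seq.as_array(seq)
        for name, lseq in library.items():
            larr = _seq.as_array(lseq)
            cls = classes.get(name, name)
            hits.extend(_scan_one(chrom, garr, name, cls, larr, "+",
                                  seed_len, min_identity, min_len))
            hits.extend(_scan_one(chrom, _seq.revcomp(garr), name, cls, larr,
                                  "-", seed_len, min_identity, min_len))
    hits.sort(key=lambda h: (h.chrom, h.start, h.end, h.strand, h.element))
    for i, h in enumerate(hits):
        h.hit_id = i
    return hits


# ---------------------------------------------------------------------------
# Overlap resolution
# ---------------------------------------------------------------------------

def resolve_overlaps(hits: list[RepeatHit], shorten_cov: float = 0.90,
                     min_rest: int = 50) -> list[RepeatHit]:
    """Priority-based overlap removal.

    Hits are admitted by descending score.  A lower-scoring hit overlapped
    by the retained annotation is shortened to its uncovered remainder(s)
    iff the overlap covers less than ``shorten_cov`` of it and each
    remainder keeps at least ``min_rest`` bp (a hit overlapped in its
    middle may split in two); otherwise it is removed.  The result is free
    of overlapping bases.
    """
    order = sorted(hits, key=lambda h: (-h.score, h.chrom, h.start, h.end,
                                        h.element, h.strand))
    retained: dict[str, list[tuple[int, int]]] = {}
    out: list[RepeatHit] = []
    for h in order:
        ivs = retained.setdefault(h.chrom, [])
        i = bisect_right(ivs, (h.start, h.start)) - 1
        overl = []
        j = max(i, 0)
        while j < len(ivs) and ivs[j][0] < h.end:
            if ivs[j][1] > h.start:
                overl.append((max(ivs[j][0], h.start), min(ivs[j][1], h.end)))
            j += 1
        cov = sum(e - s for s, e in overl)
        if cov == 0:
            pieces = [(h.start, h.end)]
        elif cov >= shorten_cov * h.length:
            continue
        else:
            pieces = []
            cur = h.start
            for s, e in overl:
                if s > cur:
                    pieces.append((cur, s))
                cur = max(cur, e)
            if cur < h.end:
                pieces.append((cur, h.end))
            if any(e - s < min_rest for s, e in pieces) or not pieces:
                continue
        for s, e in pieces:
            out.append(replace(h, start=s, end=e, trimmed=(s, e) != (h.start, h.end),
                               score=h.score * (e - s) / h.length))
            insort(ivs, (s, e))
    out.sort(key=lambda h: (h.chrom, h.start))
    return out


# ---------------------------------------------------------------------------
# Knob arrays
# ---------------------------------------------------------------------------

def find_knob_arrays(genome: dict[str, object],
                     monomers: dict[str, object] | None = None,
                     min_identity: float = 0.70,
                     max_unit_gap: int = 50) -> list[KnobArray]:
    """Annotate tandem satellite arrays by homology to the knob monomers.

    Monomer hits (one per tandem unit) are chained into an array when
    consecutive same-type hits lie within ``max_unit_gap`` bp; the unit
    count is the number of chained hits.  Defaults to the bundled synthetic
    stand-in monomers.
    """
    monomers = monomers or _seq.default_knob_monomers()
    hits = homology_scan(genome, monomers, min_identity=min_identity,
                         min_len=60, seed_len=12)
    hits = resolve_overlaps(hits, min_rest=60)
    arrays: list[KnobArray] = []
    by_key: dict[tuple[str, str], list[RepeatHit]] = {}
    for h in hits:
        by_key.setdefault((h.chrom, h.element), []).append(h)
    for (chrom, monomer), hh in sorted(by_key.items()):
        hh.sort(key=lambda h: h.start)
        group = [hh[0]]
        for h in hh[1:]:
            if h.start - group[-1].end <= max_unit_gap:
                group.append(h)
            else:
                arrays.append(_emit_array(chrom, monomer, group))
                group = [h]
        arrays.append(_emit_array(chrom, monomer, group))
    arrays.sort(key=lambda a: (a.chrom, a.start))
    return arrays


def _emit_array(chrom, monomer, group):
    return KnobArray(chrom=chrom, start=group[0].start, end=group[-1].end,
                     monomer=monomer, unit_count=len(group),
                     mean_identity=float(np.mean([h.identity for h in group])))


# ---------------------------------------------------------------------------
# Gene neighbourhood
# ---------------------------------------------------------------------------

def gene_neighborhood(genes: pd.DataFrame, annotation,
                      expression: pd.DataFrame | None = None
                      ) -> list[NeighborhoodRecord]:
    """Strand-aware upstream distance from each gene's 5' end to the
    nearest annotated element edge, per element class, optionally joined
    with max-over-conditions expression.

    ``genes`` needs columns gene_id, chrom, start, end, strand;
    ``annotation`` is a list of RepeatHit and/or KnobArray;
    ``expression`` (optional) has columns gene_id, condition, tpm.
    """
    by_class: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for el in annotation:
        cls = el.element_class if isinstance(el, RepeatHit) else el.monomer
        by_class.setdefault(cls, {}).setdefault(el.chrom, []).append(
            (el.start, el.end))
    for cls in by_class:
        for c in by_class[cls]:
            by_class[cls][c].sort()
    max_tpm = None
    if expression is not None and len(expression):
        max_tpm = expression.groupby("gene_id")["tpm"].max()
    out = []
    for g in genes.itertuples():
        tss = g.start if g.strand == "+" else g.end
        tpm = None
        if max_tpm is not None:
            tpm = float(max_tpm[g.gene_id]) if g.gene_id in max_tpm.index else None
        for cls, chroms in sorted(by_class.items()):
            ivs = chroms.get(g.chrom)
            if not ivs:
                out.append(NeighborhoodRecord(g.gene_id, cls, None, tpm))
                continue
            dist = None
            if g.strand == "+":
                # nearest element edge at or upstream of the TSS
                i = bisect_right(ivs, (tss, 1 << 62)) - 1
                cand = []
                if i >= 0:
                    s, e = ivs[i]
                    cand.append(0 if e > tss else tss - e)
                if i + 1 < len(ivs) and ivs[i + 1][0] <= g.end:
                    cand.append(0)          # element inside the gene body
                dist = min(cand) if cand else None
            else:
                i = bisect_right(ivs, (tss, 1 << 62))
                cand = []
                if i < len(ivs):
                    s, e = ivs[i]
                    cand.append(0 if s < tss else s - tss)
                if i - 1 >= 0 and ivs[i - 1][1] > g.start:
                    cand.append(0)
                dist = min(cand) if cand else None
            out.append(NeighborhoodRecord(g.gene_id, cls, dist, tpm))
    return out
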