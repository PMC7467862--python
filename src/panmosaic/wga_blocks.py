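"""Whole-genome alignment blocks: SAB/MAB construction and per-line
core / group-specific / unaligned partitioning.

The module consumes pairwise alignments from two sources: an internal
anchor-based aligner (:func:`align_pair`) suited to the near-identical,
inversion-free genomes of the synthetic panel and other desk-scale inputs,
or MUMmer ``show-coords`` text output (:func:`read_coords`) for
chromosome-scale real data.  Downstream of that entry point the processing
follows the pangenome recipe: greedy best one-to-one filtering into single
alignment blocks (SABs, >=500 bp), chaining of order-adjacent SABs into
merged alignment blocks (MABs), per-base superposition of all pairwise
blocks onto each line, and classification of every base by how many lines
of each clade it aligns to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import _seq
from .errors import ConfigError, ConsistencyError, InputError, ParseError

__all__ = [
    "RawAlignment", "SAB", "MAB", "CoverageProfile", "GenomePartition",
    "AnchorIndex", "align_pair", "read_coords", "select_sabs", "chain_mabs",
    "project_coverage", "classify_partition",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class RawAlignment:
    """One pairwise local alignment segment (0-based half-open intervals)."""

    ref_line: str
    qry_line: str
    ref_chrom: str
    qry_chrom: str
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    orientation: str          # "+" or "-"
    identity: float           # matches / alignment columns
    length: int               # alignment columns

    @property
    def score(self) -> float:
        return self.identity * self.length


@dataclass
class SAB(RawAlignment):
    """Single alignment block after best one-to-one filtering."""

    sab_id: int = -1
    is_interchromosomal: bool = False


@dataclass
class MAB:
    """Maximal chain of SABs directly adjacent (in rank order) in both
    genomes with consistent orientation."""

    mab_id: int
    sab_ids: list[int]
    ref_chrom: str
    qry_chrom: str
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    orientation: str


@dataclass
class CoverageProfile:
    """Per-base alignment participation of one line, split by partner clade.

    ``counts[chrom]`` is a pair of small-int arrays (group A partners,
    group B partners); each partner line contributes at most 1 per base.
    """

    line: str
    group_of: dict[str, str]
    counts: dict[str, tuple[np.ndarray, np.ndarray]]

    def total(self, chrom: str) -> np.ndarray:
        a, b = self.counts[chrom]
        return a.astype(np.int32) + b

    def rle(self, chrom: str) -> pd.DataFrame:
        a, b = self.counts[chrom]
        key = a.astype(np.int32) * 1000 + b
        edges = np.flatnonzero(np.diff(key)) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [key.size]])
        return pd.DataFrame(dict(start=starts, end=ends,
                                 count_a=a[starts], count_b=b[starts]))


@dataclass
class GenomePartition:
    """Disjoint labelled intervals tiling one line's genome."""

    line: str
    core_k: int
    intervals: pd.DataFrame      # chrom, start, end, label

    LABELS = ("core", "group_specific", "unaligned", "other")

    def fractions(self) -> dict[str, float]:
        df = self.intervals
        total = float((df.end - df.start).sum())
        out = {}
        for lab in self.LABELS:
            sub = df[df.label == lab]
            out[lab] = float((sub.end - sub.start).sum()) / total if total else 0.0
        return out

    def label_intervals(self, label: str) -> pd.DataFrame:
        return self.intervals[self.intervals.label == label]

    def to_bed(self, path):
        with open(path, "w") as fh:
            for r in self.intervals.itertuples():
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


# ---------------------------------------------------------------------------
# Internal aligner
# ---------------------------------------------------------------------------

class AnchorIndex:
    """Genome-wide index of unique k-mers (one strand).

    Building the index once per genome lets all pairwise alignments of a
    panel reuse it.
    """

    def __init__(self, genome: dict[str, np.ndarray], k: int = 20):
        self.k = k
        self.chroms = list(genome)
        self.lengths = {c: int(genome[c].size) for c in self.chroms}
        self.offsets = np.concatenate(
            [[0], np.cumsum([self.lengths[c] for c in self.chroms])])
        codes_parts, pos_parts = [], []
        for ci, c in enumerate(self.chroms):
            arr = _seq.as_array(genome[c])
            codes = _seq.kmer_codes(arr, k)
            codes_parts.append(codes)
            pos_parts.append(np.arange(codes.size, dtype=np.int64)
                             + self.offsets[ci])
        allcodes = np.concatenate(codes_parts) if codes_parts else np.empty(0, np.uint64)
        allpos = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        order = np.argsort(allcodes, kind="stable")
        allcodes, allpos = allcodes[order], allpos[order]
        # keep k-mers occurring exactly once
        uniq = np.ones(allcodes.size, dtype=bool)
        if allcodes.size > 1:
            dup = allcodes[1:] == allcodes[:-1]
            uniq[1:] &= ~dup
            uniq[:-1] &= ~dup
        self.codes = allcodes[uniq]
        self.pos = allpos[uniq]

    def locate(self, gpos: np.ndarray):
        """Global positions -> (chrom index, local position)."""
        ci = np.searchsorted(self.offsets, gpos, side="right") - 1
        return ci, gpos - self.offsets[ci]


def _chain_anchors(pa, pb, k, max_gap):
    """Split same-diagonal anchor lists into maximal chains."""
    order = np.argsort(pa, kind="stable")
    pa, pb = pa[order], pb[order]
    diag = pb - pa
    brk = np.flatnonzero((np.diff(diag) != 0) | (np.diff(pa) > max_gap)) + 1
    starts = np.concatenate([[0], brk])
    ends = np.concatenate([brk, [pa.size]])
    return [(pa[s], pa[e - 1] + k, pb[s], pb[e - 1] + k)
            for s, e in zip(starts, ends)]


def _extend_exact(a, b, sa, ea, sb, eb):
    """Extend a gapless block with exact matches on both ends (chunked)."""
    chunk = 256
    while sa > 0 and sb > 0:
        n = min(chunk, sa, sb)
        eq = (a[sa - n:sa] == b[sb - n:sb])[::-1]
        m = n if eq.all() else int(np.argmin(eq))
        sa -= m
        sb -= m
        if m < n:
            break
    while ea < a.size and eb < b.size:
        n = min(chunk, a.size - ea, b.size - eb)
        eq = a[ea:ea + n] == b[eb:eb + n]
        m = n if eq.all() else int(np.argmin(eq))
        ea += m
        eb += m
        if m < n:
            break
    return sa, ea, sb, eb


def align_pair(genome_a, genome_b, ref_line: str = "A", qry_line: str = "B",
               min_cluster: int = 250, anchor_len: int = 20,
               max_anchor_gap: int = 5000, both_strands: bool = True,
               index_a: AnchorIndex | None = None,
               index_b: AnchorIndex | None = None,
               index_b_rc: AnchorIndex | None = None) -> list[RawAlignment]:
    """Pairwise alignment of two genomes into gapless collinear blocks.

    Unique ``anchor_len``-mers shared by both genomes are chained along
    common diagonals; chains closer than ``max_anchor_gap`` on the same
    diagonal are fused, ends are extended by exact matches, and blocks
    shorter than ``min_cluster`` are discarded.  Identity counts matching
    columns over the full block (substitution-only blocks by construction).
    Pre-built :class:`AnchorIndex` objects may be passed to amortise the
    indexing across a panel's pairs.
    """
    genome_a = {c: _seq.as_array(s) for c, s in genome_a.items()}
    genome_b = {c: _seq.as_array(s) for c, s in genome_b.items()}
    if not genome_a or not genome_b:
        raise InputError("align_pair requires nonempty genomes")
    ia = index_a or AnchorIndex(genome_a, anchor_len)
    ib = index_b or AnchorIndex(genome_b, anchor_len)
    out: list[RawAlignment] = []

    def _collect(ib_strand: AnchorIndex, genome_b_strand, orientation):
        _, ka, kb = np.intersect1d(ia.codes, ib_strand.codes,
                                   assume_unique=True, return_indices=True)
        if ka.size == 0:
            return
        ca, la = ia.locate(ia.pos[ka])
        cb, lb = ib_strand.locate(ib_strand.pos[kb])
        pairkey = ca.astype(np.int64) * len(ib_strand.chroms) + cb
        for key in np.unique(pairkey):
            sel = pairkey == key
            ci_a = int(key) // len(ib_strand.chroms)
            ci_b = int(key) % len(ib_strand.chroms)
            chrom_a = ia.chroms[ci_a]
            chrom_b = ib_strand.chroms[ci_b]
            a_arr = genome_a[chrom_a]
            b_arr = genome_b_strand[chrom_b]
            for sa, ea, sb, eb in _chain_anchors(la[sel], lb[sel],
                                                 anchor_len, max_anchor_gap):
                sa, ea, sb, eb = _extend_exact(a_arr, b_arr, int(sa), int(ea),
                                               int(sb), int(eb))
                length = ea - sa
                if length < min_cluster:
                    continue
                ident = _seq.hamming_identity(a_arr[sa:ea], b_arr[sb:eb])
                if orientation == "+":
                    qs, qe = sb, eb
                else:
                    L = ib.lengths[chrom_b]
                    qs, qe = L - eb, L - sb
                out.append(RawAlignment(
                    ref_line, qry_line, chrom_a, chrom_b, int(sa), int(ea),
                    int(qs), int(qe), orientation, ident, int(length)))

    _collect(ib, genome_b, "+")
    if both_strands:
        genome_b_rc = {c: _seq.revcomp(s) for c, s in genome_b.items()}
        ib_rc = index_b_rc or AnchorIndex(genome_b_rc, anchor_len)
        _collect(ib_rc, genome_b_rc, "-")
    out.sort(key=lambda r: (r.ref_chrom, r.ref_start, r.qry_chrom, r.qry_start))
    return out


# ---------------------------------------------------------------------------
# MUMmer entry point
# ---------------------------------------------------------------------------

def read_coords(path, ref_line: str = "ref", qry_line: str = "qry") -> list[RawAlignment]:
    """Parse MUMmer ``show-coords -rclTH``-style tab output.

    Expected columns: S1 E1 S2 E2 LEN1 LEN2 %IDY [LENR LENQ COVR COVQ]
    REF_TAG QRY_TAG.  Input coordinates are 1-based inclusive; query
    start > end encodes the reverse strand.
    """
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t") if "\t" in raw else raw.split()
            if len(parts) not in (9, 11, 13):
                raise ParseError(f"{path}:{lineno}: expected 9/11/13 columns, "
                                 f"got {len(parts)}")
            try:
                s1, e1, s2, e2 = (int(x) for x in parts[:4])
                len1 = int(parts[4])
                idy = float(parts[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            ref_chrom, qry_chrom = parts[-2], parts[-1]
            if s2 <= e2:
                orientation, qs, qe = "+", s2 - 1, e2
            else:
                orientation, qs, qe = "-", e2 - 1, s2
            out.append(RawAlignment(ref_line, qry_line, ref_chrom, qry_chrom,
                                    s1 - 1, e1, qs, qe, orientation,
                                    idy / 100.0, len1))
    return out


# ---------------------------------------------------------------------------
# SAB selection
# ---------------------------------------------------------------------------

def _free_piece(tree: IntervalTree, start: int, end: int):
    """Largest single free (uncovered) sub-interval of [start, end) w.r.t.
    the retained intervals; returns None when coverage splits the candidate
    into more than one piece or covers it entirely."""
    ov = sorted((max(iv.begin, start), min(iv.end, end))
                for iv in tree.overlap(start, end))
    if not ov:
        return start, end
    merged = []
    for b, e in ov:
        if merged and b <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((b, e))
    pieces = []
    cur = start
    for b, e in merged:
        if b > cur:
            pieces.append((cur, b))
        cur = max(cur, e)
    if cur < end:
        pieces.append((cur, end))
    if len(pieces) != 1:
        return None
    return pieces[0]


def select_sabs(raw: list[RawAlignment], min_len: int = 500,
                transloc_min_identity: float = 0.99,
                transloc_max_overlap: int = 10) -> list[SAB]:
    """Greedy best one-to-one selection of alignment blocks.

    Candidates are processed by descending score (identity x length); a
    candidate overlapped at an end by already-retained blocks is trimmed
    (equally on both coordinates -- exact for gapless internal blocks),
    one overlapped in its middle or trimmed below ``min_len`` is removed.
    Interchromosomal candidates additionally require
    ``identity >= transloc_min_identity`` and end overlaps of at most
    ``transloc_max_overlap`` bp.
    """
    order = sorted(range(len(raw)),
                   key=lambda i: (-raw[i].score, raw[i].ref_chrom,
                                  raw[i].ref_start, raw[i].qry_chrom,
                                  raw[i].qry_start))
    ref_trees: dict[str, IntervalTree] = {}
    qry_trees: dict[str, IntervalTree] = {}
    kept: list[SAB] = []
    for i in order:
        r = raw[i]
        inter = r.ref_chrom != r.qry_chrom
        if inter and r.identity < transloc_min_identity:
            continue
        rs, re_ = r.ref_start, r.ref_end
        qs, qe = r.qry_start, r.qry_end
        rtree = ref_trees.setdefault(r.ref_chrom, IntervalTree())
        qtree = qry_trees.setdefault(r.qry_chrom, IntervalTree())
        ok = True
        for _ in range(4):
            piece = _free_piece(rtree, rs, re_)
            if piece is None:
                ok = False
                break
            lt, rt = piece[0] - rs, re_ - piece[1]
            if inter and (lt > transloc_max_overlap or rt > transloc_max_overlap):
                ok = False
                break
            rs, re_ = piece
            if r.orientation == "+":
                qs, qe = qs + lt, qe - rt
            else:
                qs, qe = qs + rt, qe - lt
            piece = _free_piece(qtree, qs, qe)
            if piece is None:
                ok = False
                break
            lt, rt = piece[0] - qs, qe - piece[1]
            if inter and (lt > transloc_max_overlap or rt > transloc_max_overlap):
                ok = False
                break
            qs, qe = piece
            if r.orientation == "+":
                rs2, re2 = rs + lt, re_ - rt
            else:
                rs2, re2 = rs + rt, re_ - lt
            if (rs2, re2) == (rs, re_):
                break
            rs, re_ = rs2, re2
        if not ok or re_ - rs < min_len or qe - qs < 1:
            continue
        rtree.addi(rs, re_)
        qtree.addi(qs, qe)
        kept.append(SAB(r.ref_line, r.qry_line, r.ref_chrom, r.qry_chrom,
                        rs, re_, qs, qe, r.orientation, r.identity,
                        re_ - rs, is_interchromosomal=inter))
    kept.sort(key=lambda s: (s.ref_chrom, s.ref_start))
    for sid, s in enumerate(kept):
        s.sab_id = sid
    return kept


# ---------------------------------------------------------------------------
# MAB chaining
# ---------------------------------------------------------------------------

def chain_mabs(sabs: list[SAB]) -> list[MAB]:
    """Partition SABs into maximal chains that are rank-adjacent in BOTH
    genomes with consistent orientation (gaps of any size allowed)."""
    if not sabs:
        return []
    by_ref = sorted(sabs, key=lambda s: (s.ref_chrom, s.ref_start))
    by_qry = sorted(sabs, key=lambda s: (s.qry_chrom, s.qry_start))
    qry_rank = {id(s): i for i, s in enumerate(by_qry)}
    mabs: list[MAB] = []
    chain = [by_ref[0]]

    def _flush():
        members = sorted(chain, key=lambda s: s.ref_start)
        mabs.append(MAB(
            mab_id=len(mabs), sab_ids=[s.sab_id for s in members],
            ref_chrom=members[0].ref_chrom, qry_chrom=members[0].qry_chrom,
            ref_start=members[0].ref_start, ref_end=members[-1].ref_end,
            qry_start=min(s.qry_start for s in members),
            qry_end=max(s.qry_end for s in members),
            orientation=members[0].orientation))

    for prev, cur in zip(by_ref, by_ref[1:]):
        adjacent = (
            cur.ref_chrom == prev.ref_chrom
            and cur.qry_chrom == prev.qry_chrom
            and cur.orientation == prev.orientation
            and qry_rank[id(cur)] - qry_rank[id(prev)]
            == (1 if prev.orientation == "+" else -1))
        if adjacent:
            chain.append(cur)
        else:
            _flush()
            chain = [cur]
    _flush()
    return mabs


# ---------------------------------------------------------------------------
# Coverage projection & partition
# ---------------------------------------------------------------------------

def project_coverage(line: str, sab_sets: dict[tuple[str, str], list[SAB]],
                     group_of: dict[str, str],
                     chrom_lengths: dict[str, int],
                     include_interchromosomal: bool = False) -> CoverageProfile:
    """Superimpose all pairwise SABs involving ``line`` onto its coordinates,
    counting each partner line at most once per base, split by the partner's
    clade.  Interchromosomal blocks are excluded by default (they mostly
    reflect paralogy)."""
    counts = {c: (np.zeros(n, dtype=np.int16), np.zeros(n, dtype=np.int16))
              for c, n in chrom_lengths.items()}
    partners = [p for p in group_of if p != line]
    for partner in partners:
        cover = {c: np.zeros(n + 1, dtype=np.int32)
                 for c, n in chrom_lengths.items()}
        found = False
        for (a, b), sabs in sab_sets.items():
            if {a, b} != {line, partner}:
                continue
            found = True
            for s in sabs:
                if s.is_interchromosomal and not include_interchromosomal:
                    continue
                if a == line:
                    chrom, lo, hi = s.ref_chrom, s.ref_start, s.ref_end
                else:
                    chrom, lo, hi = s.qry_chrom, s.qry_start, s.qry_end
                if chrom not in cover:
                    raise ConsistencyError(
                        f"SAB references unknown chromosome {chrom} of {line}")
                cover[chrom][lo] += 1
                cover[chrom][hi] -= 1
        if not found:
            raise InputError(f"no SAB set for pair ({line}, {partner})")
        gi = 0 if group_of[partner] == "A" else 1
        for c in counts:
            depth = np.cumsum(cover[c][:-1])
            counts[c][gi][depth > 0] += 1
    return CoverageProfile(line=line, group_of=dict(group_of), counts=counts)


def classify_partition(profile: CoverageProfile, core_k: int,
                       group_of: dict[str, str] | None = None) -> GenomePartition:
    """Label every base of a line's genome:

    * ``unaligned``      -- aligned to no other line;
    * ``group_specific`` -- aligned to every line of its own clade and to
      none of the other clade;
    * ``core``           -- aligned to at least ``core_k`` other lines;
    * ``other``          -- the remainder.
    """
    group_of = group_of or profile.group_of
    n_lines = len(group_of)
    if core_k > n_lines - 1:
        raise ConfigError(f"core_k={core_k} exceeds partner count {n_lines - 1}")
    own = group_of[profile.line]
    n_own_partners = sum(1 for l, g in group_of.items()
                         if g == own and l != profile.line)
    rows = []
    for chrom, (a, b) in profile.counts.items():
        own_cnt, other_cnt = (a, b) if own == "A" else (b, a)
        total = own_cnt.astype(np.int32) + other_cnt
        lab = np.full(total.size, 3, dtype=np.int8)          # other
        lab[total >= core_k] = 0                             # core
        gs = (own_cnt == n_own_partners) & (other_cnt == 0)
        lab[gs] = 1                                          # group_specific
        lab[total == 0] = 2                                  # unaligned
        edges = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [lab.size]])
        names = np.array(GenomePartition.LABELS)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e), names[lab[s]]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return GenomePartition(line=profile.line, core_k=core_k, intervals=df)
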