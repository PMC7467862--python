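"""Orthologous SNP calling from reprojected core blocks.

One reference line's ``core`` intervals are pushed through the pairwise
SABs into every other line, producing :class:`CoreBlock` records with one
interval per line.  Reference intervals are split at every partner SAB
boundary so that each emitted block maps one-to-one and unambiguously in
all lines ("complete"); leftovers are kept as "partial" and excluded from
SNP calling by default.  Near-identical per-block sequences are stacked
into a multiple alignment (trivially columnwise for the equal-length,
substitution-only blocks the panel produces; centre-star with affine-gap
pairwise steps otherwise) and every gap-free polymorphic column becomes a
SNP site with a genomic coordinate in every line.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from ._alignment import needleman_wunsch_affine
from .errors import ConsistencyError, InputError

__all__ = ["CoreBlock", "BlockAlignment", "SnpMatrix",
           "reproject_core", "align_block", "call_snps", "build_snp_matrix"]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class CoreBlock:
    """A reference core interval reprojected into all lines.

    ``spans[line] = (chrom, start, end, orientation)``; orientation is the
    strand of the line's segment relative to the reference.
    """

    block_id: int
    reference: str
    spans: dict[str, tuple[str, int, int, str]]
    status: str                      # "complete" | "partial"

    def length(self) -> int:
        c, s, e, _ = self.spans[self.reference]
        return e - s


@dataclass
class BlockAlignment:
    """Multiple alignment of one core block (rows over A,C,G,T,-)."""

    block_id: int
    rows: dict[str, str]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))


class SnpMatrix:
    """Orthologous SNP sites with per-line alleles and coordinates.

    Arrays are parallel over sites, ordered by (block, column):
    ``alleles`` (n_sites x n_lines, uint8 base codes), ``positions``
    (n_sites x n_lines), ``block_ids`` and ``chroms`` per site.
    """

    def __init__(self, lines, block_ids, chroms, alleles, positions):
        self.lines = list(lines)
        self.block_ids = np.asarray(block_ids, dtype=np.int64)
        self.chroms = np.asarray(chroms)
        self.alleles = np.asarray(alleles, dtype=np.uint8)
        self.positions = np.asarray(positions, dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return self.block_ids.size

    def line_index(self, line: str) -> int:
        return self.lines.index(line)

    def pair_match(self, line_i: str, line_j: str) -> np.ndarray:
        """Boolean per-site vector: do the two lines carry the same allele?"""
        ai = self.alleles[:, self.line_index(line_i)]
        aj = self.alleles[:, self.line_index(line_j)]
        return ai == aj

    def to_dataframe(self) -> pd.DataFrame:
        data = dict(site=np.arange(self.n_sites), block=self.block_ids,
                    chrom=self.chroms)
        for i, ln in enumerate(self.lines):
            data[f"pos_{ln}"] = self.positions[:, i]
            data[f"allele_{ln}"] = _seq.BASES[self.alleles[:, i]].view("S1").astype(str)
        return pd.DataFrame(data)

    def to_tsv(self, path):
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_vcf(self, path, reference_line: str | None = None):
        """Minimal multi-sample VCF: one pseudo-sample per line, REF = the
        reprojection reference's allele, coordinates on the reference."""
        ref = reference_line or self.lines[0]
        ri = self.line_index(ref)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.lines) + "\n")
            for i in range(self.n_sites):
                refa = int(self.alleles[i, ri])
                alts = sorted({int(a) for a in self.alleles[i]} - {refa})
                code = {refa: 0, **{a: j + 1 for j, a in enumerate(alts)}}
                gts = "\t".join(str(code[int(a)]) for a in self.alleles[i])
                fh.write(f"{self.chroms[i]}\t{self.positions[i, ri] + 1}\t"
                         f"site{i}\t{_seq.BASES[refa:refa+1].tobytes().decode()}\t"
                         + ",".join(_seq.BASES[a:a+1].tobytes().decode()
                                    for a in alts)
                         + f"\t.\tPASS\t.\tGT\t{gts}\n")

    @classmethod
    def from_tsv(cls, path) -> "SnpMatrix":
        df = pd.read_csv(path, sep="\t")
        lines = [c[4:] for c in df.columns if c.startswith("pos_")]
        alleles = np.stack([_seq.encode("".join(df[f"allele_{ln}"]))
                            for ln in lines], axis=1)
        positions = np.stack([df[f"pos_{ln}"].to_numpy() for ln in lines], axis=1)
        return cls(lines, df["block"].to_numpy(), df["chrom"].to_numpy(),
                   alleles, positions)


# ---------------------------------------------------------------------------
# Reprojection
# ---------------------------------------------------------------------------

def _oriented_sabs(reference, sab_sets):
    """Per partner: SABs of the (reference, partner) pair re-oriented so the
    reference is the 'ref' side, grouped and sorted per reference chrom."""
    out: dict[str, dict[str, list]] = {}
    for (a, b), sabs in sab_sets.items():
        if reference not in (a, b):
            continue
        partner = b if a == reference else a
        d = out.setdefault(partner, {})
        for s in sabs:
            if s.is_interchromosomal:
                continue
            if a == reference:
                rec = (s.ref_start, s.ref_end, s.qry_start, s.qry_end,
                       s.qry_chrom, s.orientation)
                chrom = s.ref_chrom
            else:
                rec = (s.qry_start, s.qry_end, s.ref_start, s.ref_end,
                       s.ref_chrom, s.orientation)
                chrom = s.qry_chrom
            d.setdefault(chrom, []).append(rec)
    for d in out.values():
        for chrom in d:
            d[chrom].sort()
    return out


def reproject_core(reference_line: str, partition, sab_sets,
                   min_block_len: int = 200) -> list[CoreBlock]:
    """Map the reference line's core intervals through every pairwise SAB.

    Each merged reference core interval is split at all partner SAB
    boundaries; a resulting segment is a *complete* block when every
    partner covers it with exactly one SAB (one unambiguous interval per
    line), otherwise *partial*.  Segments shorter than ``min_block_len``
    are dropped.
    """
    partner_sabs = _oriented_sabs(reference_line, sab_sets)
    partners = sorted(partner_sabs)
    core = partition.label_intervals("core")
    blocks: list[CoreBlock] = []
    bid = 0
    for chrom, sub in core.groupby("chrom", sort=True):
        ivs = sub.sort_values("start")[["start", "end"]].to_numpy()
        # merge touching intervals
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([int(s), int(e)])
        # partner SAB boundary positions on this chrom
        per_partner = []
        cuts_all = []
        for p in partners:
            recs = partner_sabs[p].get(chrom, [])
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            per_partner.append((recs, starts, ends))
            cuts_all.append(starts)
            cuts_all.append(ends)
        cuts = (np.unique(np.concatenate(cuts_all)) if cuts_all
                else np.empty(0, dtype=np.int64))
        for s, e in merged:
            inner = cuts[(cuts > s) & (cuts < e)]
            bounds = np.concatenate([[s], inner, [e]])
            for seg_s, seg_e in zip(bounds[:-1], bounds[1:]):
                seg_s, seg_e = int(seg_s), int(seg_e)
                if seg_e - seg_s < min_block_len:
                    continue
                spans = {reference_line: (chrom, seg_s, seg_e, "+")}
                complete = True
                for p, (recs, starts, ends) in zip(partners, per_partner):
                    i = bisect_right(starts, seg_s) - 1
                    if i < 0 or ends[i] < seg_e:
                        complete = False
                        continue
                    rs, re_, qs, qe, qchrom, orient = recs[i]
                    if orient == "+":
                        ms, me = qs + (seg_s - rs), qs + (seg_e - rs)
                    else:
                        ms, me = qe - (seg_e - rs), qe - (seg_s - rs)
                    spans[p] = (qchrom, ms, me, orient)
                blocks.append(CoreBlock(bid, reference_line, spans,
                                        "complete" if complete else "partial"))
                bid += 1
    return blocks


# ---------------------------------------------------------------------------
# Block MSA
# ---------------------------------------------------------------------------

def align_block(sequences: dict[str, object], block_id: int = 0,
                center: str | None = None) -> BlockAlignment:
    """Multiple alignment of near-identical block sequences.

    Equal-length inputs take the trivial columnwise alignment (exact for
    the substitution-only blocks reprojection produces).  Otherwise a
    centre-star progressive alignment is built: every sequence is aligned
    to the centre (the reference line, or the first key) with affine-gap
    Needleman–Wunsch and merged under "once a gap, always a gap".
    """
    if len(sequences) < 2:
        raise InputError("align_block needs at least two sequences")
    seqs = {ln: _seq.as_array(s) for ln, s in sequences.items()}
    for ln, s in seqs.items():
        if s.size == 0:
            raise InputError(f"empty sequence for line {ln}")
    lengths = {s.size for s in seqs.values()}
    if len(lengths) == 1:
        return BlockAlignment(block_id, {ln: _seq.decode(s)
                                         for ln, s in seqs.items()})
    center = center if center in seqs else next(iter(seqs))
    c_arr = seqs[center]
    # per-partner pairwise alignments to the centre
    pair_aln = {}
    for ln, s in seqs.items():
        if ln == center:
            continue
        pair_aln[ln] = needleman_wunsch_affine(c_arr, s)
    # merged gap structure on centre coordinates: gaps[i] = max gap run
    # inserted AFTER centre position i-1 (i=0: before the first base)
    gaps = np.zeros(c_arr.size + 1, dtype=np.int64)
    for ac, _ in pair_aln.values():
        ci = 0
        run = 0
        for ch in ac:
            if ch == "-":
                run += 1
            else:
                gaps[ci] = max(gaps[ci], run)
                run = 0
                ci += 1
        gaps[ci] = max(gaps[ci], run)
    rows = {}
    # centre row
    out = []
    for i in range(c_arr.size + 1):
        out.append("-" * int(gaps[i]))
        if i < c_arr.size:
            out.append(_seq.decode(c_arr[i:i + 1]))
    rows[center] = "".join(out)
    ncol = len(rows[center])
    for ln, (ac, al) in pair_aln.items():
        out = []
        ci = 0
        pend = []
        for cch, lch in zip(ac, al):
            if cch == "-":
                pend.append(lch)
            else:
                out.append("".join(pend) + "-" * int(gaps[ci] - len(pend)))
                out.append(lch)
                pend = []
                ci += 1
        out.append("".join(pend) + "-" * int(gaps[ci] - len(pend)))
        row = "".join(out)
        assert len(row) == ncol
        rows[ln] = row
    return BlockAlignment(block_id, rows)


# ---------------------------------------------------------------------------
# SNP calling
# ---------------------------------------------------------------------------

def call_snps(alignments: list[BlockAlignment], blocks: list[CoreBlock],
              lines: list[str] | None = None) -> SnpMatrix:
    """Emit SNP sites from block alignments.

    Columns containing any gap are skipped (indels are not genotyped);
    monomorphic columns are skipped; every emitted site carries one
    genomic coordinate per line, derived from the block span and the
    ungapped offset (orientation-aware).
    """
    block_map = {b.block_id: b for b in blocks}
    if lines is None:
        first = block_map[alignments[0].block_id] if alignments else None
        lines = sorted(first.spans) if first else []
    gap = ord("-")
    all_blocks, all_chroms, all_alleles, all_pos = [], [], [], []
    for aln in alignments:
        blk = block_map[aln.block_id]
        mat = np.stack([np.frombuffer(aln.rows[ln].encode(), dtype=np.uint8)
                        for ln in lines])
        ungapped = (mat != gap)
        for k, ln in enumerate(lines):
            chrom, s, e, orient = blk.spans[ln]
            if int(ungapped[k].sum()) != e - s:
                raise ConsistencyError(
                    f"block {blk.block_id}: row length does not match span of {ln}")
        keep = ungapped.all(axis=0)
        poly = keep & (mat != mat[0]).any(axis=0)
        if not poly.any():
            continue
        cols = np.flatnonzero(poly)
        offsets = np.cumsum(ungapped, axis=1) - 1      # per-row ungapped index
        pos = np.empty((cols.size, len(lines)), dtype=np.int64)
        for k, ln in enumerate(lines):
            chrom, s, e, orient = blk.spans[ln]
            off = offsets[k, cols]
            pos[:, k] = s + off if orient == "+" else e - 1 - off
        codes = _seq.encode(bytes(mat[:, cols].T.reshape(-1)))
        all_alleles.append(codes.reshape(cols.size, len(lines)))
        all_pos.append(pos)
        all_blocks.append(np.full(cols.size, blk.block_id, dtype=np.int64))
        ref_chrom = blk.spans[blk.reference][0]
        all_chroms.append(np.full(cols.size, ref_chrom, dtype=object))
    if not all_blocks:
        return SnpMatrix(lines, np.empty(0, np.int64), np.empty(0, object),
                         np.empty((0, len(lines)), np.uint8),
                         np.empty((0, len(lines)), np.int64))
    return SnpMatrix(lines,
                     np.concatenate(all_blocks),
                     np.concatenate(all_chroms),
                     np.vstack(all_alleles),
                     np.vstack(all_pos))


def build_snp_matrix(panel, blocks: list[CoreBlock],
                     complete_only: bool = True) -> SnpMatrix:
    """Extract block sequences from panel genomes, align, and call SNPs.

    Orientation-minus spans are reverse-complemented before stacking so all
    rows read in reference direction.
    """
    use = [b for b in blocks if (b.status == "complete" or not complete_only)
           and len(b.spans) >= 2]
    lines = sorted({ln for b in use for ln in b.spans})
    alignments = []
    for b in use:
        if set(b.spans) != set(lines):
            continue
        seqs = {}
        for ln, (chrom, s, e, orient) in b.spans.items():
            arr = panel.seqs[ln][chrom][s:e]
            seqs[ln] = arr if orient == "+" else _seq.revcomp(arr)
        alignments.append(align_block(seqs, block_id=b.block_id,
                                      center=b.reference))
    return call_snps(alignments, use, lines)
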