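"""Multi-line genome panel simulator with machine-readable ground truth.

The simulator emulates a small pangenome panel in the style of the European
flint / US dent maize comparison: six inbred-like lines on a known two-clade
phylogeny, accumulating substitutions along branches, gaining LTR
retrotransposon insertions (with target-site duplications and subsequently
diverging LTR pairs), tandem satellite ("knob") arrays of 180/202-bp
monomers, gene gains (often tandem duplications), and identity-by-descent
(IBD) tracts shared across arbitrary line subsets.  Every planted event is
recorded in a :class:`TruthSet` so downstream detection stages have an exact
acceptance surface.

Design notes
------------
* Genomes are gap-free relative to the ancestor except at planted insertion
  events; there is no indel evolution, no recombination and no rate
  heterogeneity.  Substitutions are Jukes–Cantor-like (uniform across sites,
  equal exchange).
* "Ancestral coordinates" refers to the ancestor *after* pre-divergence
  (ancestral) TE insertions are built into it; every line carries a strictly
  monotone map between ancestral and line coordinates.
* Branch insertions are applied at the end of their branch, never nest inside
  other planted events, and avoid IBD tract regions so that tract splices
  stay length-preserving.
* IBD tracts are realised last, by copying one carrier's evolved segment over
  the other carriers at orthologous coordinates, then applying a small
  post-copy substitution rate per carrier so tracts are near-identical
  (~99% SNP-level identity by default) rather than byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import _seq
from .errors import ConfigError, InputError, SimulationError

__all__ = [
    "TreeNode",
    "default_tree",
    "IbdTractSpec",
    "PanelConfig",
    "GenomePanel",
    "TruthSet",
    "simulate_ancestor",
    "evolve_panel",
    "simulate_panel",
    "write_panel",
    "gene_score_table",
]

_EDGE_MARGIN = 2000


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Rooted phylogeny node; ``length`` is the branch above the node in
    expected substitutions per site (0 for the root)."""

    name: str
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def iter_nodes(self):
        yield self
        for c in self.children:
            yield from c.iter_nodes()

    def branches(self):
        """All non-root branches as (node, leaf set below)."""
        for node in self.iter_nodes():
            if node.length > 0 or node is not self:
                yield node, tuple(node.leaves())


def default_tree() -> TreeNode:
    """Two-clade topology: four flint-like lines (fl1–fl4) vs two dent-like
    lines (dt1, dt2).  Terminal branches carry most of the divergence so that
    the SNP identity probability of any line pair stays in the ~0.65–0.70
    band where the expected null run of identical SNPs is far below the
    40-site haplotype seed."""
    t, u, s = 0.0015, 0.0002, 0.0002
    return TreeNode("root", 0.0, [
        TreeNode("stemA", s, [
            TreeNode("nodeA12", u, [TreeNode("fl1", t), TreeNode("fl2", t)]),
            TreeNode("nodeA34", u, [TreeNode("fl3", t), TreeNode("fl4", t)]),
        ]),
        TreeNode("stemB", s, [TreeNode("dt1", t), TreeNode("dt2", t)]),
    ])


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IbdTractSpec:
    """One planted IBD tract family: ``count`` tracts of ``length`` bp shared
    identically by the lines in ``subset``."""

    subset: tuple[str, ...]
    length: int
    count: int = 1


def default_ibd_tracts() -> list[IbdTractSpec]:
    """20 tracts, 100–400 kb, mixing within-clade, cross-clade and
    higher-order subsets; includes one flint-clade-wide tract whose 15-bit
    pairwise pattern is the planted clade-distinctive haplotype."""
    P = IbdTractSpec
    return [
        P(("fl1", "fl2", "fl3", "fl4"), 400_000),
        P(("dt1", "dt2"), 300_000),
        P(("fl1", "fl2"), 350_000),
        P(("fl1", "fl3"), 250_000),
        P(("fl2", "fl4"), 200_000),
        P(("fl3", "fl4"), 300_000),
        P(("fl2", "fl3"), 150_000),
        P(("fl1", "fl4"), 100_000),
        P(("fl1", "dt1"), 400_000),
        P(("fl2", "dt2"), 250_000),
        P(("fl4", "dt1"), 150_000),
        P(("fl3", "dt2"), 200_000),
        P(("fl2", "dt1"), 150_000),
        P(("fl3", "dt1"), 100_000),
        P(("fl4", "dt2"), 250_000),
        P(("fl1", "fl2", "fl3"), 250_000),
        P(("fl2", "fl3", "fl4"), 150_000),
        P(("fl1", "dt1", "dt2"), 200_000),
        P(("fl2", "fl3", "dt2"), 180_000),
        P(("fl1", "fl3", "fl4"), 150_000),
    ]


def _default_group_of() -> dict[str, str]:
    return {"fl1": "A", "fl2": "A", "fl3": "A", "fl4": "A",
            "dt1": "B", "dt2": "B"}


@dataclass
class PanelConfig:
    """Study conditions for one simulated panel.

    Rates are expressed as: branch lengths in expected substitutions/site,
    ``snp_rate`` a unitless multiplier on them, ``te_insertion_rate`` and
    ``gene_gain_rate`` expected events per (non-root) branch.
    """

    n_lines: int = 6
    group_of: dict[str, str] = field(default_factory=_default_group_of)
    tree: TreeNode = field(default_factory=default_tree)
    genome_length: int = 10_000_000
    chromosome_count: int = 2
    snp_rate: float = 1.0
    te_insertion_rate: float = 12.0
    ancestral_te_count: int = 40
    knob_seed_sites: int = 8
    ibd_tracts: list[IbdTractSpec] = field(default_factory=default_ibd_tracts)
    ibd_divergence: float = 1e-5      # post-copy subs/bp per carrier
    gene_count: int = 240             # ancestral genes
    gene_gain_rate: float = 5.0       # gains per branch
    tandem_fraction: float = 0.6      # fraction of gains that are tandem dups
    gene_length: tuple[int, int] = (900, 2400)
    gene_knob_margin: int = 1200      # knob arrays keep this distance to genes
    event_margin: int = 1500
    tract_margin: int = 1000
    gc: float = 0.47
    expression_conditions: int = 7
    rng_seed: int = 0

    def __post_init__(self):
        leaves = sorted(self.tree.leaves())
        if self.n_lines < 2:
            raise ConfigError("n_lines must be >= 2")
        if sorted(self.group_of) != leaves or len(leaves) != self.n_lines:
            raise ConfigError("tree leaf set, group_of keys and n_lines must agree")
        if set(self.group_of.values()) - {"A", "B"}:
            raise ConfigError("groups must be 'A' or 'B'")
        for rate in (self.snp_rate, self.te_insertion_rate, self.gene_gain_rate,
                     self.ibd_divergence):
            if rate < 0:
                raise ConfigError("rates must be non-negative")
        for spec in self.ibd_tracts:
            unknown = set(spec.subset) - set(leaves)
            if unknown:
                raise ConfigError(f"IBD tract subset has unknown lines {unknown}")
            if len(spec.subset) < 2:
                raise ConfigError("IBD tract subsets need at least two lines")

    @property
    def lines(self) -> list[str]:
        return sorted(self.tree.leaves())

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.chromosome_count)]


# ---------------------------------------------------------------------------
# Panel + truth containers
# ---------------------------------------------------------------------------

@dataclass
class GenomePanel:
    """N labelled genomes (uint8 arrays per chromosome) with clade labels."""

    lines: list[str]
    group_of: dict[str, str]
    seqs: dict[str, dict[str, np.ndarray]]

    def genome(self, line: str) -> dict[str, np.ndarray]:
        return self.seqs[line]

    def chrom_lengths(self, line: str) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs[line].items()}

    def sequence_str(self, line: str, chrom: str) -> str:
        return _seq.decode(self.seqs[line][chrom])


class TruthSet:
    """Ground-truth tables for one simulated panel (all pandas DataFrames).

    Attributes
    ----------
    snps : one row per substitution address; per-line position/allele columns.
    te_events / te_loci : per planted LTR element, and its per-carrier
        coordinates (element span and both LTR spans).
    knob_events / knob_loci : tandem satellite arrays.
    gene_events / gene_loci : ancestral genes and branch gene gains.
    ibd_events / ibd_loci : planted IBD tracts and their per-carrier spans.
    coord_maps : strictly monotone ancestral<->line segment maps.
    expression : synthetic per-line TPM across conditions.
    """

    def __init__(self, snps, te_events, te_loci, knob_events, knob_loci,
                 gene_events, gene_loci, ibd_events, ibd_loci, coord_maps,
                 expression):
        self.snps = snps
        self.te_events = te_events
        self.te_loci = te_loci
        self.knob_events = knob_events
        self.knob_loci = knob_loci
        self.gene_events = gene_events
        self.gene_loci = gene_loci
        self.ibd_events = ibd_events
        self.ibd_loci = ibd_loci
        self.coord_maps = coord_maps
        self.expression = expression

    def carriers_of_te(self, event_id: str) -> set[str]:
        return set(self.te_loci.loc[self.te_loci.event_id == event_id, "line"])

    def map_anc_to_line(self, line: str, chrom: str, pos) -> np.ndarray:
        """Map ancestral positions to `line` coordinates (must be mappable,
        i.e. lie in inherited segments)."""
        seg = self.coord_maps[(self.coord_maps.line == line)
                              & (self.coord_maps.chrom == chrom)]
        a0 = seg.anc_start.to_numpy()
        a1 = seg.anc_end.to_numpy()
        s0 = seg.line_start.to_numpy()
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        idx = np.searchsorted(a0, pos, side="right") - 1
        if (idx < 0).any() or (pos >= a1[idx.clip(0)]).any():
            raise InputError("ancestral position not inherited by this line")
        return s0[idx] + (pos - a0[idx])

    def map_line_to_anc(self, line: str, chrom: str, pos) -> np.ndarray:
        """Inverse map; positions inside line-specific insertions raise."""
        seg = self.coord_maps[(self.coord_maps.line == line)
                              & (self.coord_maps.chrom == chrom)]
        s0 = seg.line_start.to_numpy()
        a0 = seg.anc_start.to_numpy()
        ln = (seg.anc_end - seg.anc_start).to_numpy()
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        idx = np.searchsorted(s0, pos, side="right") - 1
        if (idx < 0).any() or (pos >= (s0 + ln)[idx.clip(0)]).any():
            raise InputError("line position has no ancestral counterpart")
        return a0[idx] + (pos - s0[idx])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def simulate_ancestor(length: int, gc: float = 0.47, seed: int = 0) -> np.ndarray:
    """Random ancestral sequence of exactly ``length`` bases over ACGT."""
    if length <= 0:
        raise InputError(f"ancestor length must be positive, got {length}")
    rng = np.random.default_rng(seed)
    return _seq.random_sequence(length, gc, rng)


# -- internal event records --------------------------------------------------

@dataclass
class _TE:
    event_id: str
    branch: str
    chrom: str
    anc_pos: int                  # insertion point (ancestral coords); -1 for ancestral TEs
    seq: np.ndarray               # full element (LTR + internal + LTR)
    ltr_len: int
    tsd_len: int
    superfamily: str
    domains: tuple[str, ...]
    planted_ltr_divergence: float


@dataclass
class _Knob:
    event_id: str
    branch: str
    chrom: str
    anc_pos: int
    monomer: str
    unit_count: int
    seq: np.ndarray


@dataclass
class _GeneGain:
    event_id: str
    branch: str
    chrom: str
    anc_pos: int
    kind: str                     # "gain" or "tandem"
    tandem_group: str | None
    parent_origin: str | None
    length: int


def _make_element(rng: np.random.Generator, eid: str, branch: str, chrom: str,
                  anc_pos: int, gc: float, ltr_divergence: float = 0.0) -> _TE:
    """Build one fl-LTR element: identical terminal repeats around an internal
    domain region; optionally pre-diverge the two LTRs (ancestral elements)."""
    ltr_len = int(rng.integers(250, 701))
    internal_len = int(rng.integers(4000, 9001))
    ltr = _seq.random_sequence(ltr_len, gc, rng)
    internal = _seq.random_sequence(internal_len, gc, rng)
    ltr5 = ltr.copy()
    ltr3 = ltr.copy()
    if ltr_divergence > 0:
        for copy_arr in (ltr5, ltr3):
            n = rng.poisson(ltr_divergence / 2.0 * ltr_len)
            _seq.mutate(copy_arr, int(n), rng)
    u = rng.random()
    if u < 0.6:
        fam, domains = "RLG", ("GAG", "PR", "RT", "RH", "INT")
    elif u < 0.9:
        fam, domains = "RLC", ("GAG", "PR", "INT", "RT", "RH")
    else:
        fam, domains = "RLX", ("GAG", "PR", "RT", "RH")   # INT lost
    seq = np.concatenate([ltr5, internal, ltr3])
    tsd_len = int(rng.integers(4, 7))
    return _TE(eid, branch, chrom, anc_pos, seq, ltr_len, tsd_len, fam,
               domains, ltr_divergence)


class _Blocks:
    """Provenance blocks of one evolving chromosome: a sequence is a
    concatenation of inherited ancestral segments and atomic insertion
    blocks.  Gives O(log n) coordinate maps in both directions."""

    def __init__(self, length: int):
        # (length, kind, ref) with kind 'anc' (ref = anc start) or 'ins'
        # (ref = event id)
        self.blocks: list[tuple[int, str, object]] = [(length, "anc", 0)]

    def copy(self) -> "_Blocks":
        b = _Blocks.__new__(_Blocks)
        b.blocks = list(self.blocks)
        return b

    def starts(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum([b[0] for b in self.blocks])])

    def address_of(self, pos: np.ndarray):
        """Vectorised node-position -> (kind codes, key, offset).

        kind code 0 = ancestral (key = ancestral position),
        kind code 1 = insertion (key = index into self.blocks)."""
        starts = self.starts()
        idx = np.searchsorted(starts, pos, side="right") - 1
        off = pos - starts[idx]
        kinds = np.zeros(len(pos), dtype=np.int8)
        keys = np.zeros(len(pos), dtype=np.int64)
        for j, bi in enumerate(idx):
            ln, kind, ref = self.blocks[bi]
            if kind == "anc":
                keys[j] = ref + off[j]
            else:
                kinds[j] = 1
                keys[j] = bi
        return kinds, keys, off, idx

    def anc_to_node(self, anc_pos: int) -> int:
        node = 0
        for ln, kind, ref in self.blocks:
            if kind == "anc" and ref <= anc_pos < ref + ln:
                return node + (anc_pos - ref)
            node += ln
        raise SimulationError(f"ancestral position {anc_pos} not present")

    def insert(self, inserts: list[tuple[int, str, int]]):
        """Apply insertions given as (node_pos, event_id, length); positions
        refer to the CURRENT (pre-insertion) coordinates and always fall
        inside ancestral blocks."""
        new: list[tuple[int, str, object]] = []
        node = 0
        it = iter(sorted(inserts))
        cur = next(it, None)
        for ln, kind, ref in self.blocks:
            start, remaining, rref = node, ln, ref
            while cur is not None and start <= cur[0] < node + ln:
                p, eid, elen = cur
                if kind != "anc":
                    raise SimulationError("insertion point inside planted event")
                left = p - start
                if left > 0:
                    new.append((left, "anc", rref))
                new.append((elen, "ins", eid))
                rref += left
                remaining -= left
                start = p
                cur = next(it, None)
            if remaining > 0:
                new.append((remaining, kind, rref))
            node += ln
        self.blocks = new

    def event_intervals(self) -> dict[str, tuple[int, int]]:
        out = {}
        node = 0
        for ln, kind, ref in self.blocks:
            if kind == "ins":
                out[ref] = (node, node + ln)
            node += ln
        return out

    def anc_segments(self) -> list[tuple[int, int, int]]:
        """(anc_start, anc_end, node_start) for inherited segments, merged."""
        segs = []
        node = 0
        for ln, kind, ref in self.blocks:
            if kind == "anc":
                if segs and segs[-1][1] == ref and segs[-1][2] + (segs[-1][1] - segs[-1][0]) == node:
                    a0, a1, s0 = segs[-1]
                    segs[-1] = (a0, ref + ln, s0)
                else:
                    segs.append((ref, ref + ln, node))
            node += ln
        return segs


# -- placement ---------------------------------------------------------------

def _place_tracts(rng, chrom_lens: dict[str, int], specs: list[IbdTractSpec],
                  margin: int):
    """Assign tracts to chromosomes (greedy bin packing) and lay each
    chromosome's tracts out disjointly with random gaps."""
    tracts = []  # (tract_id, subset, length)
    tid = 0
    for spec in specs:
        for _ in range(spec.count):
            tracts.append((f"ibd{tid:03d}", tuple(spec.subset), spec.length))
            tid += 1
    tracts.sort(key=lambda t: -t[2])
    load = {c: 0 for c in chrom_lens}
    assign: dict[str, list] = {c: [] for c in chrom_lens}
    for t in tracts:
        # most free capacity first
        c = min(load, key=lambda ch: (load[ch] + t[2]) / chrom_lens[ch])
        assign[c].append(t)
        load[c] += t[2] + 2 * margin
    placed = []
    min_gap = 4 * margin
    for chrom, items in assign.items():
        if not items:
            continue
        usable = chrom_lens[chrom] - 2 * _EDGE_MARGIN
        total = sum(t[2] for t in items)
        slack = usable - total - min_gap * (len(items) + 1)
        if slack < 0:
            raise SimulationError(
                f"IBD tracts ({total} bp) do not fit on {chrom} ({usable} bp usable)")
        order = list(items)
        rng.shuffle(order)
        cuts = np.sort(rng.uniform(0, slack, size=len(order) + 1))
        extra = np.diff(np.concatenate([[0], cuts])) if len(cuts) else []
        pos = _EDGE_MARGIN
        for k, (tid_, subset, length) in enumerate(order):
            pos += min_gap + int(extra[k])
            placed.append((tid_, subset, chrom, int(pos), int(pos + length)))
            pos += length
    return placed


def _sample_point(rng, chrom_lens, blocked: dict[str, IntervalTree],
                  extra: dict[str, IntervalTree] | None = None,
                  retries: int = 400) -> tuple[str, int]:
    names = list(chrom_lens)
    weights = np.array([chrom_lens[c] for c in names], dtype=float)
    weights /= weights.sum()
    for _ in range(retries):
        chrom = names[int(rng.choice(len(names), p=weights))]
        p = int(rng.integers(_EDGE_MARGIN, chrom_lens[chrom] - _EDGE_MARGIN))
        if blocked[chrom].overlaps(p):
            continue
        if extra is not None and extra[chrom].overlaps(p):
            continue
        return chrom, p
    raise SimulationError("could not place event after bounded retries")


# -- main op -----------------------------------------------------------------

def evolve_panel(ancestor: np.ndarray, config: PanelConfig):
    """Evolve ``ancestor`` down ``config.tree`` and return
    ``(GenomePanel, TruthSet)``.

    The ancestor is split into ``chromosome_count`` equal chromosomes;
    ancestral TEs are built into them (defining the ancestral coordinate
    system), then every branch applies Poisson substitutions followed by its
    insertion events, and finally IBD tracts are spliced between carriers.
    """
    ancestor = _seq.as_array(ancestor)
    if ancestor.size == 0:
        raise InputError("ancestor must be nonempty")
    rng = np.random.default_rng(config.rng_seed + 1)
    lines = config.lines
    chroms = config.chrom_names()

    # --- split ancestor & plant ancestral TEs -------------------------------
    base_len = ancestor.size // config.chromosome_count
    anc_chroms: dict[str, np.ndarray] = {}
    te_list: list[_TE] = []
    anc_te_intervals: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chroms}
    n_anc_te = config.ancestral_te_count
    eid_counter = 0
    for ci, chrom in enumerate(chroms):
        seq = ancestor[ci * base_len:(ci + 1) * base_len].copy()
        k = n_anc_te // config.chromosome_count + (
            1 if ci < n_anc_te % config.chromosome_count else 0)
        pts = []
        tree_blk = IntervalTree()
        for _ in range(k):
            for _try in range(400):
                p = int(rng.integers(_EDGE_MARGIN, seq.size - _EDGE_MARGIN))
                if not tree_blk.overlaps(p - config.event_margin,
                                         p + config.event_margin):
                    tree_blk.addi(p - config.event_margin, p + config.event_margin)
                    pts.append(p)
                    break
            else:
                raise SimulationError("ancestral TE placement failed")
        pts.sort()
        shift = 0
        pieces = []
        prev = 0
        for p in pts:
            te = _make_element(rng, f"te{eid_counter:04d}", "ancestral", chrom,
                               -1, config.gc,
                               ltr_divergence=float(rng.uniform(0.0, 0.02)))
            eid_counter += 1
            pieces.append(seq[prev:p])
            pieces.append(te.seq)
            start = p + shift
            anc_te_intervals[chrom].append((start, start + te.seq.size, te.event_id))
            te_list.append(te)
            shift += te.seq.size
            prev = p
        pieces.append(seq[prev:])
        anc_chroms[chrom] = np.concatenate(pieces) if len(pieces) > 1 else seq
    chrom_lens = {c: int(anc_chroms[c].size) for c in chroms}

    # --- IBD tract layout ---------------------------------------------------
    tracts = _place_tracts(rng, chrom_lens, config.ibd_tracts, config.tract_margin)

    blocked = {c: IntervalTree() for c in chroms}       # for branch events
    knob_extra = {c: IntervalTree() for c in chroms}    # gene perimeter for knobs
    for tid, subset, chrom, a0, a1 in tracts:
        blocked[chrom].addi(a0 - config.tract_margin, a1 + config.tract_margin)
    for chrom in chroms:
        for s, e, _eid in anc_te_intervals[chrom]:
            blocked[chrom].addi(s - config.event_margin, e + config.event_margin)

    # --- ancestral genes ----------------------------------------------------
    gene_rows = []   # origin_id, kind, branch, chrom, anc interval, tandem_group
    anc_gene_intervals: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chroms}
    gene_taken = {c: IntervalTree() for c in chroms}   # TEs + already placed genes
    gene_block_iv: dict[str, tuple[str, int, int]] = {}
    in_tract = {c: IntervalTree() for c in chroms}
    for tid, subset, chrom, a0, a1 in tracts:
        in_tract[chrom].addi(a0, a1)
    for chrom in chroms:
        for s, e, _eid in anc_te_intervals[chrom]:
            gene_taken[chrom].addi(s - 150, e + 150)
    for gi in range(config.gene_count):
        glen = int(rng.integers(*config.gene_length))
        for _try in range(400):
            chrom = chroms[int(rng.integers(len(chroms)))]
            p = int(rng.integers(_EDGE_MARGIN, chrom_lens[chrom] - _EDGE_MARGIN - glen))
            # genes may sit inside IBD tracts but not inside/too close to TEs
            # or other genes (leave room for one tandem duplicate downstream)
            if not gene_taken[chrom].overlaps(p - 200, p + 2 * glen + 600):
                break
        else:
            raise SimulationError("ancestral gene placement failed")
        origin = f"g{gi:04d}"
        anc_gene_intervals[chrom].append((p, p + glen, origin))
        gene_rows.append(dict(origin_id=origin, kind="ancestral", branch="ancestral",
                              chrom=chrom, anc_pos=p, length=glen,
                              tandem_group=None, parent_origin=None))
        gene_taken[chrom].addi(p - 200, p + 2 * glen + 600)
        blocked[chrom].addi(p - 300, p + glen + 300)
        gene_block_iv[origin] = (chrom, p - 300, p + glen + 300)
        knob_extra[chrom].addi(p - config.gene_knob_margin,
                               p + glen + config.gene_knob_margin)

    # --- branch events ------------------------------------------------------
    branches = [(node, leaves) for node, leaves in config.tree.branches()
                if node.name != "root"]
    branch_events: dict[str, list] = {node.name: [] for node, _ in branches}
    monomers = {k: _seq.encode(v) for k, v in _seq.default_knob_monomers().items()}

    knob_list: list[_Knob] = []
    gain_list: list[_GeneGain] = []
    knob_branch_idx = rng.integers(0, len(branches), size=config.knob_seed_sites)
    for ki in range(config.knob_seed_sites):
        node, _leaves = branches[int(knob_branch_idx[ki])]
        chrom, p = _sample_point(rng, chrom_lens, blocked, knob_extra)
        monomer = "knob180" if rng.random() < 0.5 else "tr1_202"
        unit_count = int(np.exp(rng.uniform(0.0, np.log(500.0))))
        arr = np.tile(monomers[monomer], unit_count)
        kb = _Knob(f"knob{ki:03d}", node.name, chrom, p, monomer, unit_count, arr)
        knob_list.append(kb)
        branch_events[node.name].append(kb)
        blocked[chrom].addi(p - config.event_margin - arr.size,
                            p + config.event_margin + arr.size)
    for node, _leaves in branches:
        n_te = rng.poisson(config.te_insertion_rate)
        for _ in range(n_te):
            chrom, p = _sample_point(rng, chrom_lens, blocked)
            te = _make_element(rng, f"te{eid_counter:04d}", node.name, chrom,
                               p, config.gc)
            eid_counter += 1
            te_list.append(te)
            branch_events[node.name].append(te)
            blocked[chrom].addi(p - config.event_margin,
                                p + config.event_margin + te.seq.size)
        n_gain = rng.poisson(config.gene_gain_rate)
        for gj in range(n_gain):
            eidg = f"g{node.name}_{gj:02d}"
            if rng.random() < config.tandem_fraction and anc_gene_intervals:
                # tandem duplication of an ancestral gene, child placed just
                # downstream; only the parent's own block may overlap there
                for _try in range(200):
                    chrom = chroms[int(rng.integers(len(chroms)))]
                    cands = anc_gene_intervals[chrom]
                    if not cands:
                        continue
                    s, e, origin = cands[int(rng.integers(len(cands)))]
                    p = e + int(rng.integers(30, 200))
                    glen = e - s
                    own = gene_block_iv[origin]
                    clear = all(
                        (iv.begin, iv.end) == (own[1], own[2])
                        for iv in blocked[chrom].overlap(p - 100, p + glen + 100))
                    if not clear or in_tract[chrom].overlaps(p - 100, p + glen + 100):
                        continue
                    gg = _GeneGain(eidg, node.name, chrom, p, "tandem",
                                   tandem_group=f"tg_{origin}",
                                   parent_origin=origin, length=glen)
                    break
                else:
                    continue
            else:
                chrom, p = _sample_point(rng, chrom_lens, blocked)
                glen = int(rng.integers(*config.gene_length))
                gg = _GeneGain(eidg, node.name, chrom, p, "gain",
                               tandem_group=None, parent_origin=None, length=glen)
            gain_list.append(gg)
            branch_events[node.name].append(gg)
            blocked[gg.chrom].addi(gg.anc_pos - 400,
                                   gg.anc_pos + 400 + gg.length)

    # mark tandem groups on parents
    parent_tg = {g.parent_origin: g.tandem_group for g in gain_list
                 if g.kind == "tandem"}
    for row in gene_rows:
        if row["origin_id"] in parent_tg:
            row["tandem_group"] = parent_tg[row["origin_id"]]

    # --- tree walk ----------------------------------------------------------
    snp_records: list[tuple] = []   # (branch, chrom, kind, key, leafset)
    leaf_state: dict[str, dict[str, tuple[np.ndarray, _Blocks]]] = {
        ln: {} for ln in lines}
    novel_gene_seq: dict[str, np.ndarray] = {}

    def walk(node: TreeNode, state: dict[str, tuple[np.ndarray, _Blocks]]):
        if node.name != "root":
            new_state = {}
            leafset = tuple(sorted(node.leaves()))
            for chrom in chroms:
                seq, blocks = state[chrom]
                seq = seq.copy()
                blocks = blocks.copy()
                # substitutions first, then this branch's insertions
                lam = seq.size * config.snp_rate * node.length
                n = int(rng.poisson(lam)) if lam > 0 else 0
                if n:
                    seq, pos = _seq.mutate(seq, n, rng, record=True)
                    kinds, keys, offs, bidx = blocks.address_of(pos)
                    for kd, ky, off, bi in zip(kinds, keys, offs, bidx):
                        if kd == 0:
                            snp_records.append((node.name, chrom, "anc",
                                                int(ky), 0, leafset))
                        else:
                            eid = blocks.blocks[int(ky)][2]
                            snp_records.append((node.name, chrom, "ins",
                                                eid, int(off), leafset))
                inserts = []
                for ev in branch_events.get(node.name, []):
                    if ev.chrom != chrom:
                        continue
                    npos = blocks.anc_to_node(ev.anc_pos)
                    if isinstance(ev, _TE):
                        # duplicate the target site: T + element, so the host
                        # copy right of the insertion flanks the element too
                        tsd = seq[npos:npos + ev.tsd_len].copy()
                        payload = np.concatenate([tsd, ev.seq])
                    elif isinstance(ev, _Knob):
                        payload = ev.seq.copy()
                    else:  # gene gain
                        if ev.kind == "tandem":
                            # copy the parent's CURRENT sequence from this node
                            pseq = None
                            for s, e, origin in anc_gene_intervals[chrom]:
                                if origin == ev.parent_origin:
                                    ps = blocks.anc_to_node(s)
                                    pseq = seq[ps:ps + (e - s)].copy()
                                    break
                            payload = pseq
                            _seq.mutate(payload, int(rng.poisson(0.01 * payload.size)),
                                        rng)
                        else:
                            payload = _seq.random_sequence(ev.length, config.gc, rng)
                            novel_gene_seq[ev.event_id] = payload
                    inserts.append((npos, ev.event_id, payload))
                if inserts:
                    inserts.sort(key=lambda t: t[0])
                    pieces = []
                    prev = 0
                    for npos, eidv, payload in inserts:
                        pieces.append(seq[prev:npos])
                        pieces.append(payload)
                        prev = npos
                    pieces.append(seq[prev:])
                    seq = np.concatenate(pieces)
                    blocks.insert([(npos, eidv, payload.size)
                                   for npos, eidv, payload in inserts])
                new_state[chrom] = (seq, blocks)
            state = new_state
        if node.is_leaf:
            leaf_state[node.name] = state
        else:
            for child in node.children:
                walk(child, state)

    root_state = {c: (anc_chroms[c], _Blocks(chrom_lens[c])) for c in chroms}
    walk(config.tree, root_state)

    # --- IBD splices --------------------------------------------------------
    ibd_event_rows = []
    ibd_loci_rows = []
    for tid, subset, chrom, a0, a1 in tracts:
        donor = subset[int(rng.integers(len(subset)))]
        spans = {}
        for line in subset:
            seq, blocks = leaf_state[line][chrom]
            s = blocks.anc_to_node(a0)
            e = blocks.anc_to_node(a1 - 1) + 1
            if e - s != a1 - a0:
                raise SimulationError("IBD tract region is not length-preserving")
            spans[line] = (s, e)
        dseq = leaf_state[donor][chrom][0][spans[donor][0]:spans[donor][1]].copy()
        for line in subset:
            seq, blocks = leaf_state[line][chrom]
            s, e = spans[line]
            if line != donor:
                seq[s:e] = dseq
            # post-copy divergence per carrier (including the donor)
            lam = config.ibd_divergence * (e - s)
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n:
                sub = seq[s:e]
                sub, pos = _seq.mutate(sub, n, rng, record=True)
                for p in pos:
                    snp_records.append((f"ibd:{tid}:{line}", chrom, "anc",
                                        int(a0 + p), 0, (line,)))
            ibd_loci_rows.append(dict(tract_id=tid, line=line, chrom=chrom,
                                      start=s, end=e))
        ibd_event_rows.append(dict(tract_id=tid, subset=",".join(subset),
                                   donor=donor, chrom=chrom, anc_start=a0,
                                   anc_end=a1, length=a1 - a0))

    panel = GenomePanel(lines=lines, group_of=dict(config.group_of),
                        seqs={ln: {c: leaf_state[ln][c][0] for c in chroms}
                              for ln in lines})

    truth = _build_truth(config, panel, leaf_state, te_list, knob_list,
                         gain_list, gene_rows, anc_gene_intervals,
                         anc_te_intervals, snp_records, ibd_event_rows,
                         ibd_loci_rows, rng)
    return panel, truth


def _build_truth(config, panel, leaf_state, te_list, knob_list, gain_list,
                 gene_rows, anc_gene_intervals, anc_te_intervals, snp_records,
                 ibd_event_rows, ibd_loci_rows, rng):
    lines = panel.lines
    chroms = config.chrom_names()

    # coordinate maps
    cm_rows = []
    ins_pos: dict[str, dict[tuple[str, str], tuple[int, int]]] = {ln: {} for ln in lines}
    anc_maps: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for ln in lines:
        for chrom in chroms:
            blocks = leaf_state[ln][chrom][1]
            segs = blocks.anc_segments()
            for a0, a1, s0 in segs:
                cm_rows.append(dict(line=ln, chrom=chrom, anc_start=a0,
                                    anc_end=a1, line_start=s0))
            a0s = np.array([s[0] for s in segs])
            a1s = np.array([s[1] for s in segs])
            s0s = np.array([s[2] for s in segs])
            anc_maps[(ln, chrom)] = (a0s, a1s, s0s)
            for eid, (s, e) in blocks.event_intervals().items():
                ins_pos[ln][(chrom, eid)] = (s, e)
    coord_maps = pd.DataFrame(cm_rows)

    def a2l(ln, chrom, pos):
        a0s, a1s, s0s = anc_maps[(ln, chrom)]
        i = int(np.searchsorted(a0s, pos, side="right")) - 1
        if i < 0 or pos >= a1s[i]:
            return None
        return int(s0s[i] + (pos - a0s[i]))

    # TE loci
    te_ev_rows, te_loci_rows = [], []
    anc_te_lookup = {eid: (chrom, s, e)
                     for chrom in chroms for s, e, eid in anc_te_intervals[chrom]}
    for te in te_list:
        carriers = []
        for ln in lines:
            if te.branch == "ancestral":
                chrom, s_anc, e_anc = anc_te_lookup[te.event_id]
                s = a2l(ln, chrom, s_anc)
                if s is None:
                    continue
                e = s + (e_anc - s_anc)
                span = (chrom, s, e)
            else:
                key = (te.chrom, te.event_id)
                if key not in ins_pos[ln]:
                    continue
                s, e = ins_pos[ln][key]
                s = s + te.tsd_len          # leading TSD copy is host sequence
                span = (te.chrom, s, e)
            carriers.append(ln)
            chrom_, s_, e_ = span
            te_loci_rows.append(dict(
                event_id=te.event_id, line=ln, chrom=chrom_, start=s_, end=e_,
                ltr5_start=s_, ltr5_end=s_ + te.ltr_len,
                ltr3_start=e_ - te.ltr_len, ltr3_end=e_))
        te_ev_rows.append(dict(
            event_id=te.event_id, branch=te.branch, chrom=te.chrom,
            anc_pos=te.anc_pos, superfamily=te.superfamily,
            domains=",".join(te.domains), ltr_len=te.ltr_len,
            element_len=int(te.seq.size), tsd_len=te.tsd_len,
            planted_ltr_divergence=te.planted_ltr_divergence,
            carriers=",".join(carriers)))

    # knob loci
    knob_ev_rows, knob_loci_rows = [], []
    for kb in knob_list:
        carriers = []
        for ln in lines:
            key = (kb.chrom, kb.event_id)
            if key not in ins_pos[ln]:
                continue
            s, e = ins_pos[ln][key]
            carriers.append(ln)
            knob_loci_rows.append(dict(event_id=kb.event_id, line=ln,
                                       chrom=kb.chrom, start=s, end=e))
        knob_ev_rows.append(dict(event_id=kb.event_id, branch=kb.branch,
                                 chrom=kb.chrom, monomer=kb.monomer,
                                 unit_count=kb.unit_count,
                                 carriers=",".join(carriers)))

    # genes
    gene_ev_rows, gene_loci_rows = [], []
    for row in gene_rows:
        carriers = []
        for ln in lines:
            s = a2l(ln, row["chrom"], row["anc_pos"])
            if s is None:
                continue
            carriers.append(ln)
            gene_loci_rows.append(dict(origin_id=row["origin_id"], line=ln,
                                       gene_id=f"{ln}_{row['origin_id']}",
                                       chrom=row["chrom"], start=s,
                                       end=s + row["length"], strand="+"))
        gene_ev_rows.append(dict(origin_id=row["origin_id"], kind=row["kind"],
                                 branch=row["branch"],
                                 tandem_group=row["tandem_group"] or "",
                                 length=row["length"],
                                 carriers=",".join(carriers)))
    for gg in gain_list:
        carriers = []
        for ln in lines:
            key = (gg.chrom, gg.event_id)
            if key not in ins_pos[ln]:
                continue
            s, e = ins_pos[ln][key]
            carriers.append(ln)
            gene_loci_rows.append(dict(origin_id=gg.event_id, line=ln,
                                       gene_id=f"{ln}_{gg.event_id}",
                                       chrom=gg.chrom, start=s, end=e,
                                       strand="+"))
        gene_ev_rows.append(dict(origin_id=gg.event_id, kind=gg.kind,
                                 branch=gg.branch,
                                 tandem_group=gg.tandem_group or "",
                                 length=gg.length,
                                 carriers=",".join(carriers)))

    # SNP truth: deduplicate addresses, read final per-line alleles
    snp_keys: dict[tuple, set] = {}
    for branch, chrom, kind, key, off, _leafset in snp_records:
        snp_keys.setdefault((chrom, kind, key, off), set()).add(branch)
    frames = []
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom in chroms:
        anc_keys = np.array(sorted(k[2] for k in snp_keys
                                   if k[0] == chrom and k[1] == "anc"),
                            dtype=np.int64)
        if anc_keys.size:
            cols = dict(chrom=chrom, addr_kind="anc",
                        addr_key=anc_keys.astype(str), addr_off=0,
                        branches=[",".join(sorted(snp_keys[(chrom, "anc", int(k), 0)]))
                                  for k in anc_keys])
            n_distinct = np.zeros(anc_keys.size, dtype=np.int64)
            seen = []
            for ln in lines:
                a0s, a1s, s0s = anc_maps[(ln, chrom)]
                i = np.searchsorted(a0s, anc_keys, side="right") - 1
                valid = (i >= 0) & (anc_keys < a1s[i.clip(0)])
                pos = np.where(valid, s0s[i.clip(0)] + (anc_keys - a0s[i.clip(0)]), -1)
                allele = np.full(anc_keys.size, ord("."), dtype=np.uint8)
                pv = pos[valid]
                allele[valid] = base_codes[panel.seqs[ln][chrom][pv]]
                cols[f"pos_{ln}"] = pos
                cols[f"allele_{ln}"] = allele.view("S1").astype(str)
                seen.append(np.where(valid, allele, 0))
            al = np.stack(seen)
            n_distinct = np.array([len(set(int(v) for v in al[:, j] if v > 0))
                                   for j in range(al.shape[1])])
            cols["segregating"] = n_distinct > 1
            frames.append(pd.DataFrame(cols))
        ins_items = sorted((k for k in snp_keys if k[0] == chrom and k[1] == "ins"),
                           key=lambda k: (str(k[2]), k[3]))
        rows = []
        for chrom_, _kind, key, off in ins_items:
            row = dict(chrom=chrom_, addr_kind="ins", addr_key=str(key),
                       addr_off=off,
                       branches=",".join(sorted(snp_keys[(chrom_, "ins", key, off)])))
            alleles = []
            for ln in lines:
                span = ins_pos[ln].get((chrom_, key))
                if span is None:
                    row[f"pos_{ln}"] = -1
                    row[f"allele_{ln}"] = "."
                else:
                    p = span[0] + off
                    row[f"pos_{ln}"] = p
                    a = _seq.decode(panel.seqs[ln][chrom_][p:p + 1])
                    row[f"allele_{ln}"] = a
                    alleles.append(a)
            row["segregating"] = len(set(alleles)) > 1
            rows.append(row)
        if rows:
            frames.append(pd.DataFrame(rows))
    snps = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if len(snps):
        snps.insert(0, "site_id", [f"s{j:06d}" for j in range(len(snps))])

    # synthetic expression: core-like genes expressed, gains mostly silent
    expr_rows = []
    n_cond = config.expression_conditions
    for row in gene_ev_rows:
        carriers = row["carriers"].split(",") if row["carriers"] else []
        scale = 1.0 if row["kind"] == "ancestral" else 0.04
        for ln in carriers:
            tpm = scale * rng.lognormal(mean=1.6, sigma=1.2, size=n_cond)
            for ci in range(n_cond):
                expr_rows.append(dict(line=ln, gene_id=f"{ln}_{row['origin_id']}",
                                      condition=f"cond{ci + 1}",
                                      tpm=round(float(tpm[ci]), 4)))

    return TruthSet(
        snps=snps,
        te_events=pd.DataFrame(te_ev_rows),
        te_loci=pd.DataFrame(te_loci_rows),
        knob_events=pd.DataFrame(knob_ev_rows),
        knob_loci=pd.DataFrame(knob_loci_rows),
        gene_events=pd.DataFrame(gene_ev_rows),
        gene_loci=pd.DataFrame(gene_loci_rows),
        ibd_events=pd.DataFrame(ibd_event_rows),
        ibd_loci=pd.DataFrame(ibd_loci_rows),
        coord_maps=coord_maps,
        expression=pd.DataFrame(expr_rows),
    )


def simulate_panel(config: PanelConfig | None = None):
    """Convenience wrapper: ancestor + evolution under one config."""
    config = config or PanelConfig()
    anc = simulate_ancestor(config.genome_length, config.gc, config.rng_seed)
    return evolve_panel(anc, config)


# ---------------------------------------------------------------------------
# Score table for the pan-gene stage
# ---------------------------------------------------------------------------

def gene_score_table(panel: GenomePanel, truth: TruthSet) -> pd.DataFrame:
    """Pairwise similarity scores between planted gene copies.

    Emulates the BLAST score table the pan-gene stage consumes: for every
    homology group (an origin gene plus any tandem duplicates derived from
    it), all cross-line copy pairs are scored as
    ``identity x min(length)`` from the actual extracted sequences.
    """
    loci = truth.gene_loci
    ev = truth.gene_events.set_index("origin_id")
    group_of_origin = {}
    for oid, row in ev.iterrows():
        tg = row["tandem_group"]
        group_of_origin[oid] = tg if tg else oid
    seqs = {}
    for r in loci.itertuples():
        seqs[(r.line, r.origin_id)] = panel.seqs[r.line][r.chrom][r.start:r.end]
    groups: dict[str, list] = {}
    for r in loci.itertuples():
        groups.setdefault(group_of_origin[r.origin_id], []).append(
            (r.line, r.origin_id, r.gene_id))
    rows = []
    for members in groups.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                la, oa, ga = members[i]
                lb, ob, gb = members[j]
                if la == lb:
                    continue
                sa, sb = seqs[(la, oa)], seqs[(lb, ob)]
                n = min(sa.size, sb.size)
                ident = float(np.mean(sa[:n] == sb[:n])) if n else 0.0
                rows.append(dict(line_a=la, gene_a=ga, line_b=lb, gene_b=gb,
                                 score=round(ident * n, 2)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_panel(panel: GenomePanel, truth: TruthSet, out_dir: str | Path) -> dict:
    """Write one FASTA per line plus truth tables (BED intervals, TSV events)
    and a JSON manifest with checksums.  Returns the manifest dict."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out}: {exc}") from exc
    files = []

    def _register(path: Path):
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        files.append(dict(path=path.name, sha256=digest,
                          bytes=path.stat().st_size))

    for line in panel.lines:
        path = out / f"{line}.fasta"
        with open(path, "w") as fh:
            for chrom, arr in panel.seqs[line].items():
                fh.write(f">{chrom} line={line} group={panel.group_of[line]}\n")
                s = _seq.decode(arr)
                for i in range(0, len(s), 80):
                    fh.write(s[i:i + 80] + "\n")
        _register(path)

    tsv_tables = dict(snps=truth.snps, te_events=truth.te_events,
                      knob_events=truth.knob_events,
                      gene_events=truth.gene_events,
                      ibd_events=truth.ibd_events,
                      coord_maps=truth.coord_maps,
                      expression=truth.expression,
                      gene_loci=truth.gene_loci,
                      te_loci=truth.te_loci)
    for name, df in tsv_tables.items():
        path = out / f"truth_{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        _register(path)

    for name, df in (("ibd", truth.ibd_loci), ("knobs", truth.knob_loci)):
        path = out / f"truth_{name}.bed"
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tname\tline\n")
            for r in df.itertuples():
                label = r.tract_id if name == "ibd" else r.event_id
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{label}\t{r.line}\n")
        _register(path)

    manifest = dict(lines=panel.lines, group_of=panel.group_of, files=files)
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return manifest


def read_panel_fastas(panel_dir: str | Path, manifest: dict | None = None) -> GenomePanel:
    """Reload panel genomes written by :func:`write_panel`."""
    from Bio import SeqIO
    panel_dir = Path(panel_dir)
    if manifest is None:
        manifest = json.loads((panel_dir / "manifest.json").read_text())
    seqs = {}
    for line in manifest["lines"]:
        seqs[line] = {rec.id: _seq.encode(str(rec.seq))
                      for rec in SeqIO.parse(panel_dir / f"{line}.fasta", "fasta")}
    return GenomePanel(lines=list(manifest["lines"]),
                       group_of=dict(manifest["group_of"]), seqs=seqs)
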