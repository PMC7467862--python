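"""Alignment blocks: aligner behaviour, coords parsing, SAB/MAB rules,
coverage projection and partition labels."""

import numpy as np
import pytest

from panmosaic import wga_blocks as wb
from panmosaic._seq import random_sequence, revcomp
from panmosaic.errors import ConfigError, ParseError
from panmosaic.pipeline import PanelAnalysis
from panmosaic.synthetic_panel import GenomePanel


# ---------------------------------------------------------------------------
# align_pair
# ---------------------------------------------------------------------------

def test_align_identical_sequences():
    rng = np.random.default_rng(0)
    g = {"chr1": random_sequence(50_000, 0.5, rng)}
    al = wb.align_pair(g, {"chr1": g["chr1"].copy()})
    assert len(al) == 1
    a = al[0]
    assert (a.ref_start, a.ref_end, a.orientation, a.identity) == (0, 50_000, "+", 1.0)


def test_align_unrelated_sequences_empty():
    rng = np.random.default_rng(1)
    g1 = {"chr1": random_sequence(10_000, 0.5, rng)}
    g2 = {"chr1": random_sequence(10_000, 0.5, rng)}
    assert wb.align_pair(g1, g2) == []


def test_align_reverse_complement_minus_orientation():
    rng = np.random.default_rng(2)
    g = {"chr1": random_sequence(30_000, 0.5, rng)}
    al = wb.align_pair(g, {"chr1": revcomp(g["chr1"])})
    assert len(al) == 1
    a = al[0]
    assert a.orientation == "-"
    assert (a.ref_start, a.ref_end) == (0, 30_000)
    assert (a.qry_start, a.qry_end) == (0, 30_000)
    assert a.identity == 1.0


def test_align_min_cluster_filters_short_blocks():
    rng = np.random.default_rng(3)
    shared = random_sequence(200, 0.5, rng)     # < 250 bp shared segment
    g1 = {"c": np.concatenate([random_sequence(5000, 0.5, rng), shared])}
    g2 = {"c": np.concatenate([shared, random_sequence(5000, 0.5, rng)])}
    assert wb.align_pair(g1, g2) == []


# ---------------------------------------------------------------------------
# read_coords
# ---------------------------------------------------------------------------

def test_read_coords_field_mapping(tmp_path):
    p = tmp_path / "x.coords"
    p.write_text("1\t500\t1\t500\t500\t500\t99.80\tchr1\tchr1\n")
    (a,) = wb.read_coords(p)
    assert (a.ref_start, a.ref_end) == (0, 500)
    assert (a.qry_start, a.qry_end) == (0, 500)
    assert a.orientation == "+"
    assert a.identity == pytest.approx(0.998)


def test_read_coords_reverse_strand_convention(tmp_path):
    p = tmp_path / "x.coords"
    p.write_text("1\t500\t800\t301\t500\t500\t95.00\tchr1\tchr2\n")
    (a,) = wb.read_coords(p)
    assert a.orientation == "-"
    assert (a.qry_start, a.qry_end) == (300, 800)


def test_read_coords_empty_and_malformed(tmp_path):
    p = tmp_path / "empty.coords"
    p.write_text("")
    assert wb.read_coords(p) == []
    p.write_text("1\t500\toops\n")
    with pytest.raises(ParseError, match="1"):
        wb.read_coords(p)


# ---------------------------------------------------------------------------
# select_sabs
# ---------------------------------------------------------------------------

def _raw(rs, re, qs, qe, ident=1.0, rc="chr1", qc="chr1", orient="+"):
    return wb.RawAlignment("A", "B", rc, qc, rs, re, qs, qe, orient,
                           ident, re - rs)


def test_select_sabs_minimum_size():
    assert wb.select_sabs([_raw(0, 400, 0, 400, 1.0)]) == []
    kept = wb.select_sabs([_raw(0, 600, 0, 600, 1.0)])
    assert len(kept) == 1 and kept[0].sab_id == 0


def test_select_sabs_translocation_filter():
    lo = _raw(1000, 1600, 0, 600, 0.985, qc="chr2")
    assert wb.select_sabs([lo]) == []
    neighbors = [_raw(0, 1005, 5000, 6005, 1.0), _raw(1595, 3000, 8000, 9405, 1.0)]
    hi = _raw(1000, 1600, 0, 600, 0.992, qc="chr2")
    kept = wb.select_sabs(neighbors + [hi])
    inter = [s for s in kept if s.is_interchromosomal]
    assert len(inter) == 1            # 5-bp overlaps tolerated (trimmed)
    far = _raw(980, 1600, 0, 620, 0.992, qc="chr2")   # 25-bp overlap
    kept = wb.select_sabs(neighbors + [far])
    assert not any(s.is_interchromosomal for s in kept)


def test_select_sabs_best_one_to_one_on_duplicate_interval():
    a = _raw(0, 1000, 0, 1000, 0.99)
    b = _raw(0, 1000, 5000, 6000, 0.95)
    kept = wb.select_sabs([a, b])
    assert len(kept) == 1
    assert kept[0].identity == 0.99


def test_select_sabs_one_to_one_invariant_random():
    """No base of either genome may belong to two SABs (exact check on
    random overlapping candidates)."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        cands = []
        for _k in range(12):
            rs = int(rng.integers(0, 8000))
            ln = int(rng.integers(500, 2500))
            qs = int(rng.integers(0, 8000))
            cands.append(_raw(rs, rs + ln, qs, qs + ln,
                              float(rng.uniform(0.9, 1.0))))
        kept = wb.select_sabs(cands)
        for side in ("ref", "qry"):
            ivs = sorted((getattr(s, f"{side}_start"), getattr(s, f"{side}_end"))
                         for s in kept)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2, f"overlap on {side} side"


# ---------------------------------------------------------------------------
# chain_mabs
# ---------------------------------------------------------------------------

def _sab(i, rs, re, qs, qe, orient="+"):
    return wb.SAB("A", "B", "chr1", "chr1", rs, re, qs, qe, orient, 1.0,
                  re - rs, sab_id=i)


def test_chain_mabs_collinear_chain():
    sabs = [_sab(0, 0, 100, 0, 100), _sab(1, 200, 300, 150, 250),
            _sab(2, 400, 500, 300, 400)]
    mabs = wb.chain_mabs(sabs)
    assert len(mabs) == 1
    assert mabs[0].sab_ids == [0, 1, 2]


def test_chain_mabs_order_inconsistency_splits():
    sabs = [_sab(0, 0, 100, 200, 300), _sab(1, 200, 300, 0, 100)]
    mabs = wb.chain_mabs(sabs)
    assert sorted(len(m.sab_ids) for m in mabs) == [1, 1]


def test_chain_mabs_singleton_and_minus_chain():
    assert len(wb.chain_mabs([_sab(0, 0, 100, 0, 100)])) == 1
    sabs = [_sab(0, 0, 100, 300, 400, "-"), _sab(1, 200, 300, 100, 200, "-")]
    mabs = wb.chain_mabs(sabs)
    assert len(mabs) == 1 and mabs[0].orientation == "-"


def test_chain_mabs_partition_property():
    rng = np.random.default_rng(9)
    sabs = []
    pos = 0
    qpos = 0
    for i in range(30):
        ln = int(rng.integers(100, 400))
        sabs.append(_sab(i, pos, pos + ln,
                         qpos if rng.random() < 0.8 else qpos + 10_000,
                         (qpos if rng.random() < 0.8 else qpos + 10_000) + ln))
        pos += ln + int(rng.integers(10, 100))
        qpos += ln + int(rng.integers(10, 100))
    mabs = wb.chain_mabs(sabs)
    covered = sorted(i for m in mabs for i in m.sab_ids)
    assert covered == list(range(30))


# ---------------------------------------------------------------------------
# coverage + partition
# ---------------------------------------------------------------------------

def _toy_sets(line_len=1000):
    group_of = {"x": "A", "y": "A", "z": "B"}
    # partner y: two overlapping SABs on x -> counted once
    sab_xy = [
        wb.SAB("x", "y", "c", "c", 100, 400, 100, 400, "+", 1.0, 300, sab_id=0),
        wb.SAB("x", "y", "c", "c", 300, 600, 300, 600, "+", 1.0, 300, sab_id=1)]
    sab_xz = [
        wb.SAB("x", "z", "c", "c", 200, 500, 200, 500, "+", 1.0, 300, sab_id=0),
        wb.SAB("x", "z", "c", "c", 700, 900, 700, 900, "+", 1.0, 200, sab_id=1)]
    sab_yz = []
    sets = {("x", "y"): sab_xy, ("x", "z"): sab_xz, ("y", "z"): sab_yz}
    return group_of, sets


def test_project_coverage_counts_partner_once():
    group_of, sets = _toy_sets()
    prof = wb.project_coverage("x", sets, group_of, {"c": 1000})
    a, b = prof.counts["c"]
    assert a[350] == 1 and b[350] == 1          # y once despite two SABs
    assert a[150] == 1 and b[150] == 0
    assert a[0] == 0 and b[0] == 0
    assert prof.total("c")[250] == 2


def test_classify_partition_labels():
    group_of, sets = _toy_sets()
    prof = wb.project_coverage("x", sets, group_of, {"c": 1000})
    part = wb.classify_partition(prof, core_k=2)
    df = part.intervals
    def label_at(p):
        row = df[(df.start <= p) & (df.end > p)]
        return row.label.iloc[0]
    assert label_at(0) == "unaligned"
    assert label_at(150) == "group_specific"    # own-group only (y)
    assert label_at(250) == "core"              # 2 partners
    assert label_at(750) == "other"             # other-group partner only
    # tiling: interval lengths sum to genome length, disjoint & sorted
    assert (df.end - df.start).sum() == 1000
    assert (df.start.to_numpy()[1:] == df.end.to_numpy()[:-1]).all()


def test_classify_partition_core_k_validation():
    group_of, sets = _toy_sets()
    prof = wb.project_coverage("x", sets, group_of, {"c": 1000})
    with pytest.raises(ConfigError):
        wb.classify_partition(prof, core_k=5)


def test_identical_panel_limit_core_one():
    """N copies of one genome: core fraction exactly 1, unaligned 0."""
    rng = np.random.default_rng(11)
    base = {"chr1": random_sequence(200_000, 0.47, rng)}
    lines = ["fl1", "fl2", "fl3", "fl4", "dt1", "dt2"]
    panel = GenomePanel(lines=lines,
                        group_of={l: ("A" if l.startswith("fl") else "B")
                                  for l in lines},
                        seqs={l: {"chr1": base["chr1"].copy()} for l in lines})
    pa = PanelAnalysis(panel, both_strands=False)
    for ln in lines:
        fr = pa.partitions[ln].fractions()
        assert fr["core"] == 1.0
        assert fr["unaligned"] == 0.0


def test_panel_partition_tiles_genome(small_analysis):
    pa = small_analysis
    for ln in pa.lines:
        df = pa.partitions[ln].intervals
        for chrom, sub in df.groupby("chrom"):
            assert (sub.end - sub.start).sum() == len(pa.panel.seqs[ln][chrom])


def test_panel_sabs_one_to_one(small_analysis):
    for sabs in small_analysis.sab_sets.values():
        by_side = {}
        for s in sabs:
            by_side.setdefault(("r", s.ref_chrom), []).append(
                (s.ref_start, s.ref_end))
            by_side.setdefault(("q", s.qry_chrom), []).append(
                (s.qry_start, s.qry_end))
        for ivs in by_side.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2
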