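"""Repeat scan thresholds, priority overlap resolution (vs brute force),
knob arrays and gene neighbourhoods."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from helpers import brute_resolve
from panmosaic import repeat_knobs as rk
from panmosaic._seq import (decode, default_knob_monomers, encode, mutate,
                            random_sequence, revcomp)
from panmosaic.errors import InputError


def _lib(seed=0, length=500):
    rng = np.random.default_rng(seed)
    return {"rep1": random_sequence(length, 0.5, rng)}, rng


# ---------------------------------------------------------------------------
# homology_scan
# ---------------------------------------------------------------------------

def test_scan_exact_copy():
    lib, rng = _lib()
    genome = {"chr1": np.concatenate([random_sequence(3000, 0.5, rng),
                                      lib["rep1"],
                                      random_sequence(3000, 0.5, rng)])}
    hits = rk.homology_scan(genome, lib)
    plus = [h for h in hits if h.strand == "+"]
    assert len(plus) == 1
    h = plus[0]
    assert (h.start, h.end, h.identity) == (3000, 3500, 1.0)


def test_scan_minus_strand():
    lib, rng = _lib(1)
    genome = {"chr1": np.concatenate([random_sequence(2000, 0.5, rng),
                                      revcomp(lib["rep1"]),
                                      random_sequence(2000, 0.5, rng)])}
    hits = [h for h in rk.homology_scan(genome, lib) if h.identity > 0.9]
    assert len(hits) == 1 and hits[0].strand == "-"
    assert (hits[0].start, hits[0].end) == (2000, 2500)


def test_scan_length_threshold():
    lib, rng = _lib(2)
    right = random_sequence(2000, 0.5, rng)
    right[:10] = (lib["rep1"][74:84] + 1) % 4      # no lucky extension
    genome = {"chr1": np.concatenate([random_sequence(2000, 0.5, rng),
                                      lib["rep1"][:74], right])}
    assert [h for h in rk.homology_scan(genome, lib) if h.identity > 0.95] == []


def test_scan_identity_threshold():
    lib, rng = _lib(3)
    copy = lib["rep1"][:200].copy()
    mutate(copy, 110, rng)             # ~65% identity after collisions
    ident = float(np.mean(copy == lib["rep1"][:200]))
    assert ident < 0.70
    genome = {"chr1": np.concatenate([random_sequence(2000, 0.5, rng), copy,
                                      random_sequence(2000, 0.5, rng)])}
    hits = [h for h in rk.homology_scan(genome, lib)
            if h.end - h.start > 150]
    assert hits == []


def test_scan_empty_library_error():
    with pytest.raises(InputError):
        rk.homology_scan({"c": "ACGT"}, {})


# ---------------------------------------------------------------------------
# resolve_overlaps
# ---------------------------------------------------------------------------

def _hit(s, e, score, chrom="c", element="x"):
    return rk.RepeatHit(chrom, s, e, "+", element, element, 1.0, score)


def test_resolve_trim_example():
    """200-bp hit overlapped by 30 bp at one end is trimmed to 170 bp."""
    hi = _hit(0, 300, 1000.0)
    lo = _hit(270, 470, 200.0)
    out = rk.resolve_overlaps([hi, lo])
    spans = sorted((h.start, h.end) for h in out)
    assert spans == [(0, 300), (300, 470)]
    assert out[-1].length == 170


def test_resolve_remove_high_coverage():
    """100-bp hit overlapped over 95 bp (>=90% coverage) is removed."""
    hi = _hit(0, 295, 1000.0)
    lo = _hit(200, 300, 100.0)
    out = rk.resolve_overlaps([hi, lo])
    assert [(h.start, h.end) for h in out] == [(0, 295)]


def test_resolve_remove_short_rest():
    """60-bp hit with a 40-bp remainder (<50 bp) is removed."""
    hi = _hit(0, 120, 1000.0)
    lo = _hit(100, 160, 60.0)
    out = rk.resolve_overlaps([hi, lo])
    assert [(h.start, h.end) for h in out] == [(0, 120)]


def test_resolve_middle_split_both_rests():
    hi = _hit(200, 300, 1000.0)
    lo = _hit(100, 400, 250.0)
    out = rk.resolve_overlaps([hi, lo])
    spans = sorted((h.start, h.end) for h in out)
    assert spans == [(100, 200), (200, 300), (300, 400)]
    hi2 = _hit(160, 300, 1000.0)       # left remainder only 60... < min_rest?
    lo2 = _hit(100, 330, 250.0)        # remainders 60 and 30 -> removed
    out = rk.resolve_overlaps([hi2, lo2])
    assert sorted((h.start, h.end) for h in out) == [(160, 300)]


def test_resolve_zero_overlap_and_priority_properties():
    rng = np.random.default_rng(4)
    hits = [_hit(int(rng.integers(0, 3000)),
                 int(rng.integers(0, 3000)) + 100,
                 float(rng.uniform(1, 1000)), element=f"e{i}")
            for i in range(60)]
    hits = [h for h in hits if h.end > h.start]
    out = rk.resolve_overlaps(hits)
    ivs = sorted((h.start, h.end) for h in out)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        assert e1 <= s2
    union = sum(e - s for s, e in ivs)
    assert union == sum(h.length for h in out)
    top = max(hits, key=lambda h: h.score)
    kept_top = [h for h in out if h.element == top.element
                and (h.start, h.end) == (top.start, top.end)]
    assert kept_top and not kept_top[0].trimmed


def test_resolve_matches_brute_force_random_instances():
    rng = np.random.default_rng(12)
    for _ in range(300):
        hits = []
        for i in range(int(rng.integers(1, 21))):
            s = int(rng.integers(0, 1500))
            L = int(rng.integers(30, 400))
            hits.append(rk.RepeatHit("c", s, s + L, "+", f"e{i}", "r", 1.0,
                                     float(rng.uniform(1, 100))))
        out = rk.resolve_overlaps(hits)
        got = {(h.chrom, h.start, h.end, h.element) for h in out}
        assert got == brute_resolve(hits, span=3000)


@settings(deadline=None, max_examples=80, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 500), st.integers(30, 200),
                          st.floats(1, 100, allow_nan=False)),
                min_size=1, max_size=12))
def test_resolve_overlap_free_property(raw):
    hits = [rk.RepeatHit("c", s, s + L, "+", f"e{i}", "r", 1.0, sc)
            for i, (s, L, sc) in enumerate(raw)]
    out = rk.resolve_overlaps(hits)
    got = {(h.chrom, h.start, h.end, h.element) for h in out}
    assert got == brute_resolve(hits, span=1000)


# ---------------------------------------------------------------------------
# knob arrays
# ---------------------------------------------------------------------------

def test_knob_array_exact_tandem():
    monomers = default_knob_monomers()
    rng = np.random.default_rng(5)
    arr = np.tile(encode(monomers["knob180"]), 10)
    genome = {"chr1": np.concatenate([random_sequence(2000, 0.5, rng), arr,
                                      random_sequence(2000, 0.5, rng)])}
    arrays = [a for a in rk.find_knob_arrays(genome) if a.unit_count > 1]
    assert len(arrays) == 1
    a = arrays[0]
    assert a.monomer == "knob180"
    assert a.unit_count == 10
    assert a.end - a.start == 1800


def test_knob_single_monomer_cryptic_site():
    monomers = default_knob_monomers()
    rng = np.random.default_rng(6)
    genome = {"chr1": np.concatenate([random_sequence(3000, 0.5, rng),
                                      encode(monomers["tr1_202"]),
                                      random_sequence(3000, 0.5, rng)])}
    arrays = [a for a in rk.find_knob_arrays(genome) if a.monomer == "tr1_202"]
    assert len(arrays) == 1 and arrays[0].unit_count == 1


def test_knob_two_arrays_split_by_gap():
    monomers = default_knob_monomers()
    rng = np.random.default_rng(7)
    block = np.tile(encode(monomers["knob180"]), 5)
    genome = {"chr1": np.concatenate([block, random_sequence(5000, 0.5, rng),
                                      block])}
    arrays = [a for a in rk.find_knob_arrays(genome) if a.unit_count >= 5]
    assert len(arrays) == 2


def test_knob_unit_count_under_divergence():
    """Planted counts recovered exactly at 0% divergence and within 10% at
    5% divergence."""
    monomers = default_knob_monomers()
    rng = np.random.default_rng(8)
    n_units = 30
    arr = np.tile(encode(monomers["knob180"]), n_units)
    mutate(arr, int(0.05 * arr.size), rng)
    genome = {"chr1": np.concatenate([random_sequence(2000, 0.5, rng), arr,
                                      random_sequence(2000, 0.5, rng)])}
    arrays = [a for a in rk.find_knob_arrays(genome) if a.unit_count > 1]
    assert len(arrays) == 1
    assert abs(arrays[0].unit_count - n_units) <= 0.1 * n_units


# ---------------------------------------------------------------------------
# gene neighbourhood
# ---------------------------------------------------------------------------

def _genes():
    return pd.DataFrame([
        dict(gene_id="g1", chrom="chr1", start=5500, end=6500, strand="+"),
        dict(gene_id="g2", chrom="chr1", start=100, end=900, strand="-"),
        dict(gene_id="g3", chrom="chr2", start=100, end=900, strand="+"),
    ])


def test_gene_neighborhood_distances_and_sentinel():
    knob = rk.KnobArray("chr1", 4000, 5000, "knob180", 5, 1.0)
    recs = rk.gene_neighborhood(_genes(), [knob])
    by = {r.gene_id: r for r in recs}
    assert by["g1"].upstream_distance == 500       # 5500 - 5000
    assert by["g2"].upstream_distance == 3100      # 4000 - 900 (minus strand)
    assert by["g3"].upstream_distance is None      # no element on chr2


def test_gene_neighborhood_inside_element_zero():
    knob = rk.KnobArray("chr1", 5000, 7000, "knob180", 10, 1.0)
    recs = rk.gene_neighborhood(_genes(), [knob])
    assert {r.gene_id: r.upstream_distance for r in recs}["g1"] == 0


def test_gene_neighborhood_expression_join():
    expr = pd.DataFrame([("g1", "c1", 1.0), ("g1", "c2", 7.5),
                         ("g2", "c1", 0.2)],
                        columns=["gene_id", "condition", "tpm"])
    knob = rk.KnobArray("chr1", 4000, 5000, "knob180", 5, 1.0)
    recs = rk.gene_neighborhood(_genes(), [knob], expr)
    by = {r.gene_id: r for r in recs}
    assert by["g1"].max_tpm == 7.5
    assert by["g2"].max_tpm == 0.2
    assert by["g3"].max_tpm is None


def test_panel_genes_keep_knob_perimeter(small_panel):
    """Planted genes keep a >=1000-bp clearance to planted knob arrays."""
    panel, truth = small_panel
    if not len(truth.knob_loci):
        pytest.skip("no knobs planted in this panel")
    for line in panel.lines:
        genes = truth.gene_loci[truth.gene_loci.line == line].rename(
            columns={})[["gene_id", "chrom", "start", "end", "strand"]]
        arrays = [rk.KnobArray(r.chrom, r.start, r.end, "knob180", 1, 1.0)
                  for r in truth.knob_loci[truth.knob_loci.line == line]
                  .itertuples()]
        if not arrays:
            continue
        for rec in rk.gene_neighborhood(genes, arrays):
            if rec.upstream_distance is not None:
                assert rec.upstream_distance >= 1000
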