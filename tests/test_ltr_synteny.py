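"""fl-LTR filtering, classification, ages, junction clustering, sharing."""

import itertools

import numpy as np
import pytest

from panmosaic import ltr_synteny as ls
from panmosaic._seq import decode, encode, mutate, random_sequence
from panmosaic.errors import InputError


def _el(eid="e1", line="fl1", start=1000, end=9000, domains=("RT",),
        tandem=0.0):
    return ls.LtrElement(eid, line, "chr1", start, end, (start, start + 300),
                         (end - 300, end), domains=domains,
                         tandem_content=tandem)


# ---------------------------------------------------------------------------
# filtering / classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("domains,tandem,kept", [
    (("RT",), 0.10, True),
    ((), 0.10, False),                 # no retroelement domain
    (("RT",), 0.30, False),            # tandem content >= 25%
    (("GAG", "PR"), 0.0, True),
    (("XYZ",), 0.0, False),
])
def test_filter_candidates(domains, tandem, kept):
    out = ls.filter_candidates([_el(domains=domains, tandem=tandem)])
    assert bool(out) is kept


@pytest.mark.parametrize("order,family", [
    (("RT", "RH", "INT"), "RLG"),
    (("INT", "RT", "RH"), "RLC"),
    (("RT", "RH"), "RLX"),             # INT missing
    (("RH", "INT"), "RLX"),            # RT missing
    (("GAG", "PR", "RT", "RH", "INT"), "RLG"),
    (("RT", "RT", "RH", "INT"), "RLX"),  # duplicated RT
])
def test_classify_superfamily(order, family):
    assert ls.classify_superfamily(order) == family


# ---------------------------------------------------------------------------
# ages
# ---------------------------------------------------------------------------

def test_age_identical_ltrs_zero():
    s = "ACGT" * 100
    est = ls.estimate_insertion_age(s, s)
    assert est.age_years == 0.0 and est.reliable


def test_age_closed_form_hand_value():
    """26 substitutions over 10 kb: d = 0.0026 -> 100,000 years at the
    default rate 1.3e-8/site/year."""
    rng = np.random.default_rng(0)
    a = random_sequence(10_000, 0.5, rng)
    b = a.copy()
    pos = rng.choice(10_000, size=26, replace=False)
    b[pos] = (b[pos] + 1) % 4
    est = ls.estimate_insertion_age(a, b)
    assert est.divergence == pytest.approx(0.0026)
    assert est.age_years == pytest.approx(100_000.0)


def test_age_simulated_known_age():
    """LTR pairs diverged for 1 Myr are dated within 3 binomial SD."""
    mu = 1.3e-8
    T = 1_000_000
    L = 1000
    rng = np.random.default_rng(5)
    ests = []
    for _ in range(200):
        a = random_sequence(L, 0.47, rng)
        b = a.copy()
        for arr in (a, b):
            mutate(arr, int(rng.poisson(mu * T * L)), rng)
        ests.append(ls.estimate_insertion_age(a, b, mu=mu).age_years)
    mean = float(np.mean(ests))
    d_true = 2 * mu * T
    sd_sites = np.sqrt(d_true * (1 - d_true) * L * 200) / (L * 200)
    sd_age = sd_sites / (2 * mu)
    assert abs(mean - T) < 3 * sd_age + 0.02 * T   # small back-mutation bias


def test_age_unreliable_flag_and_errors():
    rng = np.random.default_rng(2)
    a = random_sequence(500, 0.5, rng)
    b = random_sequence(500, 0.5, rng)
    assert not ls.estimate_insertion_age(a, b).reliable
    with pytest.raises(InputError):
        ls.estimate_insertion_age("", "ACGT")


# ---------------------------------------------------------------------------
# junctions
# ---------------------------------------------------------------------------

def test_extract_junctions_arithmetic():
    rng = np.random.default_rng(3)
    genome = {"chr1": random_sequence(20_000, 0.5, rng)}
    el = _el(start=1000, end=9000)
    up, down = ls.extract_junctions(el, genome)
    assert up.sequence == decode(genome["chr1"][950:1050])
    assert down.sequence == decode(genome["chr1"][8950:9050])
    assert len(up.sequence) == len(down.sequence) == 100


def test_extract_junctions_near_contig_end_skipped():
    rng = np.random.default_rng(3)
    genome = {"chr1": random_sequence(5000, 0.5, rng)}
    assert ls.extract_junctions(_el(start=30, end=4000), genome) is None


def test_cluster_junctions_thresholds():
    rng = np.random.default_rng(4)
    base = decode(random_sequence(100, 0.5, rng))
    s1 = ls.JunctionSignature("a", "upstream", base)
    s2 = ls.JunctionSignature("b", "upstream", base)
    assert len(ls.cluster_junctions([s1, s2])) == 1
    # 3 mismatches in 100 bp = 97% identity: below the 98% cutoff
    arr = encode(base)
    arr[[10, 50, 90]] = (arr[[10, 50, 90]] + 1) % 4
    s3 = ls.JunctionSignature("c", "upstream", decode(arr))
    assert len(ls.cluster_junctions([s1, s3])) == 2
    # 2 mismatches = 98%: joins
    arr2 = encode(base)
    arr2[[10, 50]] = (arr2[[10, 50]] + 1) % 4
    s4 = ls.JunctionSignature("d", "upstream", decode(arr2))
    assert len(ls.cluster_junctions([s1, s4])) == 1


def test_cluster_junctions_random_all_singletons():
    rng = np.random.default_rng(6)
    sigs = [ls.JunctionSignature(f"s{i}", "upstream",
                                 decode(random_sequence(100, 0.5, rng)))
            for i in range(100)]
    clusters = ls.cluster_junctions(sigs)
    assert len(clusters) == 100
    # exhaustive oracle on the instance: no pair reaches 98% identity
    arrs = [encode(s.sequence) for s in sigs]
    for i, j in itertools.combinations(range(100), 2):
        assert np.mean(arrs[i] == arrs[j]) < 0.98


# ---------------------------------------------------------------------------
# sharing
# ---------------------------------------------------------------------------

def _fixture_elements_and_clusters():
    """Three lines; locus L1 shared by fl1+fl2, locus L2 private to dt1,
    and a second insertion of the same family elsewhere in fl1."""
    rng = np.random.default_rng(8)
    host = random_sequence(40_000, 0.5, rng)
    element = random_sequence(5000, 0.5, rng)
    genomes, elements = {}, []
    for line, at in (("fl1", 10_000), ("fl2", 10_000), ("dt1", 20_000)):
        g = np.concatenate([host[:at], element, host[at:]])
        if line == "fl1":                       # second copy, different flanks
            g = np.concatenate([g, random_sequence(2000, 0.5, rng), element,
                                random_sequence(2000, 0.5, rng)])
            elements.append(ls.LtrElement(f"{line}:x2", line, "chr1",
                                          g.size - 2000 - 5000, g.size - 2000,
                                          (0, 1), (2, 3), domains=("RT",)))
        genomes[line] = {"chr1": g}
        elements.append(ls.LtrElement(f"{line}:x1", line, "chr1", at,
                                      at + 5000, (0, 1), (2, 3),
                                      domains=("RT",)))
    sigs = []
    for el in elements:
        pair = ls.extract_junctions(el, genomes[el.line])
        sigs.extend(pair)
    return elements, ls.cluster_junctions(sigs)


def test_build_sharing_truth_fixture():
    elements, clusters = _fixture_elements_and_clusters()
    records = ls.build_sharing(clusters, elements)
    sets = sorted(tuple(sorted(r.lines)) for r in records)
    assert sets == [("dt1",), ("fl1",), ("fl1", "fl2")]
    # sharing is symmetric as a relation
    for r in records:
        for a in r.lines:
            for b in r.lines:
                assert a in r.lines and b in r.lines


def test_build_sharing_either_junction_mode():
    elements, clusters = _fixture_elements_and_clusters()
    strict = ls.build_sharing(clusters, elements, require_both=True)
    loose = ls.build_sharing(clusters, elements, require_both=False)
    assert len(loose) <= len(strict)


# ---------------------------------------------------------------------------
# pan/core + matrix
# ---------------------------------------------------------------------------

def test_pan_core_identical_and_disjoint_limits():
    lines = ["a", "b", "c"]
    same = [frozenset(lines)] * 5
    df = ls.pan_core_curve(same, lines)
    assert (df.pan == 5).all() and (df.core == 5).all()
    private = [frozenset([l]) for l in lines for _ in range(2)]
    df = ls.pan_core_curve(private, lines)
    assert df.pan.tolist() == [2.0, 4.0, 6.0]
    assert df.core.tolist()[1:] == [0.0, 0.0]


def test_pan_core_monotone_all_orderings_random_sets():
    rng = np.random.default_rng(11)
    lines = ["a", "b", "c", "d", "e", "f"]
    sets = [frozenset(rng.choice(lines, size=rng.integers(1, 7),
                                 replace=False).tolist())
            for _ in range(60)]
    for order in itertools.permutations(lines):
        pan, core = ls.pan_core_by_order(sets, list(order))
        assert (np.diff(pan) >= 0).all()
        assert (np.diff(core) <= 0).all()


def test_pairwise_sharing_matrix_limits():
    lines = ["a", "b", "c"]
    df, order = ls.pairwise_sharing_matrix([frozenset(lines)] * 4, lines)
    assert (df.to_numpy() == 1.0).all()
    df, order = ls.pairwise_sharing_matrix(
        [frozenset([l]) for l in lines], lines)
    off = df.to_numpy()[~np.eye(3, dtype=bool)]
    assert (off == 0.0).all()
    assert sorted(order) == lines


def test_gff3_roundtrip(tmp_path):
    p = tmp_path / "el.gff3"
    p.write_text("chr1\tsim\tLTR_retrotransposon\t1001\t9000\t.\t+\t.\t"
                 "ID=e1;ltr5=1001-1300;ltr3=8701-9000;domains=RT,RH,INT;"
                 "tandem_content=0.1\n")
    (el,) = ls.read_elements_gff3(p, "fl1")
    assert (el.start, el.end) == (1000, 9000)
    assert el.ltr5 == (1000, 1300) and el.ltr3 == (8700, 9000)
    assert ls.classify_superfamily(el.domains) == "RLG"


# ---------------------------------------------------------------------------
# naive detector (toy genomes)
# ---------------------------------------------------------------------------

def test_naive_detector_recovers_planted_element():
    rng = np.random.default_rng(15)
    ltr = random_sequence(400, 0.5, rng)
    internal = random_sequence(5000, 0.5, rng)
    tsd = random_sequence(5, 0.5, rng)
    host_l = random_sequence(4000, 0.5, rng)
    host_r = random_sequence(4000, 0.5, rng)
    genome = {"chr1": np.concatenate([host_l, tsd, ltr, internal, ltr, tsd,
                                      host_r])}
    (el,) = ls.detect_fl_ltr_naive(genome, "toy")
    # repeat boundaries are ambiguous by +-1 bp when flank bases coincide
    assert abs(el.start - 4005) <= 2 and abs(el.end - 9805) <= 2
    assert abs((el.ltr5[1] - el.ltr5[0]) - 400) <= 2
    assert el.ltr3[1] == el.end and el.ltr5[0] == el.start
    assert len(el.tsd) >= 4


def test_naive_detector_rejects_out_of_window():
    rng = np.random.default_rng(16)
    ltr = random_sequence(60, 0.5, rng)           # LTR below 100 bp
    internal = random_sequence(5000, 0.5, rng)
    tsd = random_sequence(5, 0.5, rng)
    genome = {"chr1": np.concatenate([random_sequence(2000, 0.5, rng), tsd,
                                      ltr, internal, ltr, tsd,
                                      random_sequence(2000, 0.5, rng)])}
    assert ls.detect_fl_ltr_naive(genome) == []
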