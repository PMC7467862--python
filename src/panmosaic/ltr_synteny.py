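"""Full-length LTR retrotransposon filtering, dating, junction clustering
and cross-line sharing.

Candidate elements (from annotation GFF3 or the simulator's truth) are
filtered for credible retroelement structure (at least one canonical
domain, tandem content < 25%), classified into Gypsy (RLG: RT-RH-INT),
Copia (RLC: INT-RT-RH) or unknown (RLX) by internal domain order, and
dated from the divergence of their two LTRs at a fixed neutral rate
(default 1.3e-8 substitutions/site/year; age T = d / (2 mu)).

Insertion loci are fingerprinted by two 100-bp junction signatures (50 bp
inside + 50 bp outside each element end).  Signatures are clustered
greedily against centroids at 98% identity / 98% coverage; two elements
from different lines share a syntenic location iff their upstream AND
downstream signatures co-cluster, with sharing sets closed transitively.
Pan/core curves and the asymmetric pairwise-sharing matrix summarise the
landscape.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from ._alignment import edlib_global
from .errors import InputError

__all__ = [
    "LtrElement", "JunctionSignature", "JunctionCluster", "SharingRecord",
    "AgeEstimate", "filter_candidates", "classify_superfamily",
    "estimate_insertion_age", "extract_junctions", "cluster_junctions",
    "build_sharing", "pan_core_curve", "pan_core_by_order",
    "pairwise_sharing_matrix", "elements_from_truth", "read_elements_gff3",
]

_DOMAINS = {"RT", "RH", "INT", "PR", "GAG"}


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class LtrElement:
    """One full-length LTR retrotransposon candidate."""

    element_id: str
    line: str
    chrom: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    domains: tuple[str, ...] = ()
    tsd: str = ""
    tandem_content: float = 0.0
    superfamily: str | None = None


@dataclass
class JunctionSignature:
    """100-bp insertion-site fingerprint (50 bp inside, 50 bp outside)."""

    element_id: str
    side: str                 # "upstream" | "downstream"
    sequence: str

    @property
    def signature_id(self) -> str:
        return f"{self.element_id}:{self.side}"


@dataclass
class JunctionCluster:
    centroid_id: str
    member_ids: list[str]


@dataclass
class SharingRecord:
    """One syntenic fl-LTR location and the lines still carrying an intact
    element there."""

    location_id: int
    lines: frozenset
    element_ids: tuple[str, ...]
    ages: dict[str, float] = field(default_factory=dict)
    ambiguous: bool = False


@dataclass
class AgeEstimate:
    age_years: float
    divergence: float
    identity: float
    reliable: bool


# ---------------------------------------------------------------------------
# Filtering and classification
# ---------------------------------------------------------------------------

def filter_candidates(candidates: list[LtrElement],
                      max_tandem_content: float = 0.25) -> list[LtrElement]:
    """Keep elements with at least one canonical retroelement domain
    (RT, RH, INT, PR, GAG) and tandem repeat content below the cutoff."""
    return [c for c in candidates
            if set(c.domains) & _DOMAINS
            and c.tandem_content < max_tandem_content]


def classify_superfamily(domain_order) -> str:
    """Gypsy/Copia/unknown classification from internal domain order:
    RT-RH-INT -> RLG, INT-RT-RH -> RLC; elements missing (or duplicating)
    INT or RT -> RLX."""
    core = tuple(d for d in domain_order if d in ("RT", "RH", "INT"))
    counts = {d: core.count(d) for d in ("RT", "RH", "INT")}
    if counts["RT"] != 1 or counts["INT"] != 1:
        return "RLX"
    if core == ("RT", "RH", "INT"):
        return "RLG"
    if core == ("INT", "RT", "RH"):
        return "RLC"
    # RH absent or misplaced: fall back on RT/INT order
    return "RLG" if core.index("RT") < core.index("INT") else "RLC"


def estimate_insertion_age(ltr5_seq, ltr3_seq, mu: float = 1.3e-8,
                           correction: str = "raw") -> AgeEstimate:
    """Insertion age from 5'/3' LTR divergence: T = d / (2 mu) years.

    ``d`` is the substitution fraction over aligned (non-gap) columns of a
    global alignment; ``correction='k2p'`` applies the Kimura two-parameter
    transform (transitions/transversions counted from the aligned pairs).
    Pairs aligning below 70% identity are flagged unreliable.
    """
    a = _seq.as_array(ltr5_seq)
    b = _seq.as_array(ltr3_seq)
    if a.size == 0 or b.size == 0:
        raise InputError("both LTR sequences must be nonempty")
    if a.size == b.size:
        eq = a == b
        columns = a.size
        subs = int((~eq).sum())
        identity = float(eq.mean())
        pairs = np.stack([a[~eq], b[~eq]])
    else:
        dist, columns, subs = edlib_global(a, b)
        identity = 1.0 - dist / columns if columns else 0.0
        pairs = None
    aligned = columns if a.size != b.size else a.size
    d = subs / aligned if aligned else 0.0
    if correction == "k2p" and d > 0:
        if pairs is not None and pairs.size:
            # transitions: A<->G (0,2), C<->T (1,3)
            ts = int((np.abs(pairs[0].astype(int) - pairs[1].astype(int)) == 2).sum())
        else:
            ts = subs // 2
        P = ts / aligned
        Qv = (subs - ts) / aligned if aligned else 0.0
        with np.errstate(invalid="raise"):
            try:
                d = -0.5 * np.log((1 - 2 * P - Qv) * np.sqrt(1 - 2 * Qv))
            except FloatingPointError:
                d = subs / aligned
    return AgeEstimate(age_years=d / (2.0 * mu), divergence=float(d),
                       identity=identity, reliable=identity >= 0.70)


# ---------------------------------------------------------------------------
# Junction signatures and clustering
# ---------------------------------------------------------------------------

def extract_junctions(element: LtrElement, genome: dict[str, np.ndarray],
                      flank: int = 50):
    """Both junction signatures of one element, or ``None`` when the
    element sits closer than ``flank`` bp to a sequence end."""
    arr = _seq.as_array(genome[element.chrom])
    s, e = element.start, element.end
    if s < flank or e + flank > arr.size:
        return None
    up = _seq.decode(arr[s - flank:s + flank])
    down = _seq.decode(arr[e - flank:e + flank])
    return (JunctionSignature(element.element_id, "upstream", up),
            JunctionSignature(element.element_id, "downstream", down))


def cluster_junctions(signatures: list[JunctionSignature],
                      min_identity: float = 0.98,
                      min_coverage: float = 0.98) -> list[JunctionCluster]:
    """Greedy centroid clustering of junction signatures.

    Signatures are processed in deterministic order (descending length,
    then signature id); each joins the first centroid whose global
    alignment satisfies both identity and mutual-coverage thresholds,
    otherwise founds a new cluster.
    """
    ordered = sorted(signatures, key=lambda s: (-len(s.sequence),
                                                s.signature_id))
    centroids: list[tuple[str, str]] = []       # (signature_id, sequence)
    members: list[list[str]] = []
    for sig in ordered:
        placed = False
        for k, (cid, cseq) in enumerate(centroids):
            la, lb = len(sig.sequence), len(cseq)
            if min(la, lb) < min_coverage * max(la, lb):
                continue
            max_d = int(max(la, lb) * (1.0 - min_identity))
            dist, cols, _subs = edlib_global(sig.sequence, cseq, max_dist=max_d)
            if dist < 0 or cols == 0:
                continue
            if 1.0 - dist / max(la, lb) >= min_identity:
                members[k].append(sig.signature_id)
                placed = True
                break
        if not placed:
            centroids.append((sig.signature_id, sig.sequence))
            members.append([sig.signature_id])
    return [JunctionCluster(cid, mem)
            for (cid, _), mem in zip(centroids, members)]


# ---------------------------------------------------------------------------
# Sharing
# ---------------------------------------------------------------------------

def build_sharing(clusters: list[JunctionCluster],
                  elements: list[LtrElement],
                  ages: dict[str, AgeEstimate] | None = None,
                  require_both: bool = True) -> list[SharingRecord]:
    """Group elements into syntenic locations.

    Default rule: elements share a location iff their upstream signatures
    co-cluster AND their downstream signatures co-cluster (the relation's
    transitive closure is taken).  ``require_both=False`` relaxes to either
    junction, via union-find over the two cluster keys.
    """
    by_id = {e.element_id: e for e in elements}
    cl_of: dict[str, int] = {}
    for k, cl in enumerate(clusters):
        for sid in cl.member_ids:
            cl_of[sid] = k
    keys: dict[str, tuple] = {}
    for eid in by_id:
        up = cl_of.get(f"{eid}:upstream")
        down = cl_of.get(f"{eid}:downstream")
        if up is None or down is None:
            continue
        keys[eid] = (up, down)
    groups: dict[object, list[str]] = {}
    if require_both:
        for eid, key in keys.items():
            groups.setdefault(key, []).append(eid)
    else:
        parent: dict[object, object] = {}

        def find(x):
            while parent.setdefault(x, x) != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x, y):
            parent[find(x)] = find(y)

        for eid, (up, down) in keys.items():
            union(("u", up), ("d", down))
        for eid, (up, down) in keys.items():
            groups.setdefault(find(("u", up)), []).append(eid)
    records = []
    for loc, eids in enumerate(sorted(groups.values(), key=lambda g: g[0])):
        lines = frozenset(by_id[e].line for e in eids)
        amb = len(eids) > len(lines)        # >1 intact element of one line
        rec_ages = {}
        if ages:
            for e in eids:
                if e in ages:
                    line = by_id[e].line
                    rec_ages[line] = min(ages[e].age_years,
                                         rec_ages.get(line, np.inf))
        records.append(SharingRecord(loc, lines, tuple(sorted(eids)),
                                     rec_ages, ambiguous=amb))
    return records


# ---------------------------------------------------------------------------
# Pan/core and pairwise summaries
# ---------------------------------------------------------------------------

def pan_core_by_order(line_sets: list[frozenset], order: list[str]):
    """Pan and core location counts for one ordering of the lines."""
    pan, core = [], []
    seen: set[str] = set()
    for line in order:
        seen.add(line)
        pan.append(sum(1 for s in line_sets if s & seen))
        core.append(sum(1 for s in line_sets if seen <= s))
    return np.array(pan), np.array(core)


def pan_core_curve(records, lines: list[str],
                   orderings: str | int = "all",
                   seed: int = 0) -> pd.DataFrame:
    """Average pan/core curve over line orderings (all permutations when
    ``orderings='all'`` and feasible, otherwise a sampled subset).
    Proportions are relative to the k=1 mean."""
    line_sets = [r.lines if isinstance(r, SharingRecord) else frozenset(r)
                 for r in records]
    if orderings == "all":
        perms = list(itertools.permutations(lines))
    else:
        rng = np.random.default_rng(seed)
        perms = [list(rng.permutation(lines)) for _ in range(int(orderings))]
    pans = np.zeros(len(lines))
    cores = np.zeros(len(lines))
    for order in perms:
        p, c = pan_core_by_order(line_sets, list(order))
        pans += p
        cores += c
    pans /= len(perms)
    cores /= len(perms)
    base = pans[0] if pans[0] else 1.0
    return pd.DataFrame(dict(k=np.arange(1, len(lines) + 1),
                             pan=pans, core=cores,
                             pan_prop=pans / base, core_prop=cores / base))


def pairwise_sharing_matrix(records, lines: list[str]):
    """Asymmetric sharing fractions: entry (A, B) = fraction of A's
    locations also present in B.  Returns (DataFrame, display order) with
    the order from average-linkage hierarchical clustering on 1 - shared.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform
    line_sets = [r.lines if isinstance(r, SharingRecord) else frozenset(r)
                 for r in records]
    n = len(lines)
    mat = np.zeros((n, n))
    for i, a in enumerate(lines):
        have_a = [s for s in line_sets if a in s]
        for j, b in enumerate(lines):
            if i == j:
                mat[i, j] = 1.0
            elif have_a:
                mat[i, j] = sum(1 for s in have_a if b in s) / len(have_a)
    df = pd.DataFrame(mat, index=lines, columns=lines)
    sym = 1.0 - (mat + mat.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    if n > 2:
        link = hierarchy.linkage(squareform(sym, checks=False), method="average")
        order = [lines[i] for i in hierarchy.leaves_list(link)]
    else:
        order = list(lines)
    return df, order


# ---------------------------------------------------------------------------
# Element I/O
# ---------------------------------------------------------------------------

def elements_from_truth(truth) -> list[LtrElement]:
    """LtrElement records for every planted element copy in a TruthSet."""
    ev = truth.te_events.set_index("event_id")
    out = []
    for r in truth.te_loci.itertuples():
        meta = ev.loc[r.event_id]
        out.append(LtrElement(
            element_id=f"{r.line}:{r.event_id}", line=r.line, chrom=r.chrom,
            start=int(r.start), end=int(r.end),
            ltr5=(int(r.ltr5_start), int(r.ltr5_end)),
            ltr3=(int(r.ltr3_start), int(r.ltr3_end)),
            domains=tuple(meta["domains"].split(",")),
            tandem_content=0.0, superfamily=meta["superfamily"]))
    return out


def detect_fl_ltr_naive(genome: dict[str, object], line: str = "line",
                        min_ltr: int = 100, max_ltr: int = 2000,
                        min_span: int = 3000, max_span: int = 25000,
                        min_tsd: int = 4, max_tsd: int = 20,
                        k: int = 20) -> list[LtrElement]:
    """Naive direct-repeat scan for full-length LTR candidates (toy genomes
    only; quadratic-ish in repeat content).

    Pairs of identical k-mers at a compatible distance seed an ungapped
    extension into a candidate LTR pair; candidates must satisfy the size
    window (LTR 100-2000 bp, span 3000-25000 bp) and carry a flanking
    target-site duplication of 4-20 bp.  Domains are left empty for the
    caller to annotate.  Overlapping candidates keep the longest element.
    """
    out = []
    for chrom, seq in genome.items():
        arr = _seq.as_array(seq)
        codes = _seq.kmer_codes(arr, k)
        order = np.argsort(codes, kind="stable")
        sc = codes[order]
        dup = np.flatnonzero((sc[1:] == sc[:-1]))
        cands = []
        seen = set()
        for t in dup:
            p1, p2 = sorted((int(order[t]), int(order[t + 1])))
            if not (min_span - max_ltr <= p2 - p1 <= max_span):
                continue
            # ungapped extension of the repeat pair
            a, b = p1, p2
            while a > 0 and b > 0 and arr[a - 1] == arr[b - 1]:
                a -= 1
                b -= 1
            e1, e2 = p1 + k, p2 + k
            while e1 < b and e2 < arr.size and arr[e1] == arr[e2]:
                e1 += 1
                e2 += 1
            ltr_len = e1 - a
            start, end = a, e2
            if not (min_ltr <= ltr_len <= max_ltr
                    and min_span <= end - start <= max_span):
                continue
            if (start, end) in seen or start < max_tsd or end + max_tsd > arr.size:
                continue
            seen.add((start, end))
            tsd = ""
            for t_len in range(max_tsd, min_tsd - 1, -1):
                if np.array_equal(arr[start - t_len:start],
                                  arr[end:end + t_len]):
                    tsd = _seq.decode(arr[start - t_len:start])
                    break
            if not tsd:
                continue
            cands.append(LtrElement(
                element_id=f"{line}:{chrom}:{start}", line=line, chrom=chrom,
                start=start, end=end, ltr5=(start, start + ltr_len),
                ltr3=(end - ltr_len, end), tsd=tsd))
        cands.sort(key=lambda e: (-(e.end - e.start), e.start))
        kept: list[LtrElement] = []
        for c in cands:
            if all(c.end <= o.start or c.start >= o.end for o in kept):
                kept.append(c)
        out.extend(sorted(kept, key=lambda e: e.start))
    return out


def read_elements_gff3(path, line: str) -> list[LtrElement]:
    """Read fl-LTR elements from GFF3 with the documented attribute schema:
    ``ID``, ``ltr5=start-end``, ``ltr3=start-end`` (1-based inclusive),
    ``domains=RT,RH,...``, optional ``tsd``, ``tandem_content``."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) != 9:
                raise InputError(f"{path}:{lineno}: GFF3 needs 9 columns")
            chrom, _src, _type, start, end, _score, _strand, _phase, attrs = parts
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if "ltr5" not in a or "ltr3" not in a:
                raise InputError(f"{path}:{lineno}: missing ltr5/ltr3 attributes")
            l5 = tuple(int(x) for x in a["ltr5"].split("-"))
            l3 = tuple(int(x) for x in a["ltr3"].split("-"))
            out.append(LtrElement(
                element_id=a.get("ID", f"{line}:{lineno}"), line=line,
                chrom=chrom, start=int(start) - 1, end=int(end),
                ltr5=(l5[0] - 1, l5[1]), ltr3=(l3[0] - 1, l3[1]),
                domains=tuple(a.get("domains", "").split(",")) if a.get("domains") else (),
                tsd=a.get("tsd", ""),
                tandem_content=float(a.get("tandem_content", 0.0))))
    return out
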