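"""Tabular I/O for pipeline products (documented TSV/BED dialects)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import InputError
from .haplotypes import HigherOrderHaplotype, PairwiseRun
from .wga_blocks import MAB, SAB

SAB_COLUMNS = ["sab_id", "ref_line", "qry_line", "ref_chrom", "ref_start",
               "ref_end", "qry_chrom", "qry_start", "qry_end", "orientation",
               "identity", "length", "is_interchromosomal"]


def sabs_to_tsv(sabs: list[SAB], path):
    rows = [[s.sab_id, s.ref_line, s.qry_line, s.ref_chrom, s.ref_start,
             s.ref_end, s.qry_chrom, s.qry_start, s.qry_end, s.orientation,
             round(s.identity, 6), s.length, int(s.is_interchromosomal)]
            for s in sabs]
    pd.DataFrame(rows, columns=SAB_COLUMNS).to_csv(path, sep="\t", index=False)


def sabs_from_tsv(path) -> list[SAB]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SAB_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing SAB columns {sorted(missing)}")
    out = []
    for r in df.itertuples():
        out.append(SAB(r.ref_line, r.qry_line, r.ref_chrom, r.qry_chrom,
                       int(r.ref_start), int(r.ref_end), int(r.qry_start),
                       int(r.qry_end), r.orientation, float(r.identity),
                       int(r.length), sab_id=int(r.sab_id),
                       is_interchromosomal=bool(r.is_interchromosomal)))
    return out


def mabs_to_tsv(mabs: list[MAB], path):
    rows = [[m.mab_id, ",".join(map(str, m.sab_ids)), m.ref_chrom,
             m.ref_start, m.ref_end, m.qry_chrom, m.qry_start, m.qry_end,
             m.orientation] for m in mabs]
    pd.DataFrame(rows, columns=["mab_id", "sab_ids", "ref_chrom", "ref_start",
                                "ref_end", "qry_chrom", "qry_start",
                                "qry_end", "orientation"]
                 ).to_csv(path, sep="\t", index=False)


def runs_to_tsv(runs: list[PairwiseRun], path):
    rows = []
    for r in runs:
        (a, b) = r.pair
        ca, sa, ea = r.spans[a]
        cb, sb, eb = r.spans[b]
        rows.append([a, b, r.block_id, r.start, r.end, r.n_sites,
                     r.n_identical, round(r.identity, 6),
                     ca, sa, ea, cb, sb, eb])
    pd.DataFrame(rows, columns=["line_a", "line_b", "block", "site_start",
                                "site_end", "n_sites", "n_identical",
                                "identity", "chrom_a", "start_a", "end_a",
                                "chrom_b", "start_b", "end_b"]
                 ).to_csv(path, sep="\t", index=False)


def hoh_to_tsv(hohs: list[HigherOrderHaplotype], lines, path):
    rows = []
    for h in hohs:
        row = [h.bitstring, h.block_id, h.start, h.end, h.n_sites]
        for ln in lines:
            c, s, e = h.spans[ln]
            row.extend([c, s, e])
        rows.append(row)
    cols = ["pattern", "block", "site_start", "site_end", "n_sites"]
    for ln in lines:
        cols.extend([f"chrom_{ln}", f"start_{ln}", f"end_{ln}"])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def sharing_to_tsv(records, path):
    rows = []
    for r in records:
        ages = ";".join(f"{ln}:{r.ages[ln]:.0f}" for ln in sorted(r.ages))
        rows.append([r.location_id, ",".join(sorted(r.lines)),
                     ",".join(r.element_ids), len(r.lines),
                     int(r.ambiguous), ages])
    pd.DataFrame(rows, columns=["location_id", "lines", "elements", "n_lines",
                                "ambiguous", "ages_years"]
                 ).to_csv(path, sep="\t", index=False)


def read_truth(panel_dir) -> "TruthSet":
    """Reconstruct a TruthSet from tables written by ``write_panel``."""
    from .synthetic_panel import TruthSet
    d = Path(panel_dir)

    def tsv(name):
        p = d / f"truth_{name}.tsv"
        if not p.exists():
            return pd.DataFrame()
        df = pd.read_csv(p, sep="\t")
        for col in ("tandem_group", "carriers", "branches"):
            if col in df.columns:
                df[col] = df[col].fillna("")
        return df

    def bed(name, cols):
        p = d / f"truth_{name}.bed"
        if not p.exists():
            return pd.DataFrame(columns=cols)
        df = pd.read_csv(p, sep="\t")
        df.columns = ["chrom", "start", "end", cols[0], "line"]
        return df[[cols[0], "line", "chrom", "start", "end"]]

    return TruthSet(
        snps=tsv("snps"), te_events=tsv("te_events"), te_loci=tsv("te_loci"),
        knob_events=tsv("knob_events"),
        knob_loci=bed("knobs", ["event_id"]),
        gene_events=tsv("gene_events"), gene_loci=tsv("gene_loci"),
        ibd_events=tsv("ibd_events"), ibd_loci=bed("ibd", ["tract_id"]),
        coord_maps=tsv("coord_maps"), expression=tsv("expression"))
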