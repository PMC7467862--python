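"""End-to-end panel analysis: WGA blocks -> partitions -> core SNPs ->
haplotype runs -> higher-order haplotypes -> fl-LTR sharing -> pan-genes.

:class:`PanelAnalysis` computes each stage lazily and caches it, so callers
(CLI, tests, reproduction script) can ask for any intermediate without
re-running the rest.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import core_snps, haplotypes, ltr_synteny, pangene, wga_blocks
from ._seq import revcomp
from .errors import InputError

__all__ = ["PanelAnalysis"]


class PanelAnalysis:
    """Lazy pipeline over one :class:`~panmosaic.synthetic_panel.GenomePanel`
    (or any equivalent dict-of-genomes container)."""

    def __init__(self, panel, truth=None, reference: str | None = None,
                 core_k: int = 4, both_strands: bool = True,
                 seed_min: int = 40, min_identity: float = 0.98):
        self.panel = panel
        self.truth = truth
        self.lines = list(panel.lines)
        self.reference = reference or self.lines[0]
        if self.reference not in self.lines:
            raise InputError(f"unknown reference line {self.reference!r}")
        self.core_k = core_k
        self.both_strands = both_strands
        self.seed_min = seed_min
        self.min_identity = min_identity
        self._cache: dict[str, object] = {}

    # -- WGA -----------------------------------------------------------------

    @property
    def sab_sets(self):
        if "sab_sets" not in self._cache:
            idx = {ln: wga_blocks.AnchorIndex(self.panel.seqs[ln])
                   for ln in self.lines}
            rc_idx = {}
            if self.both_strands:
                rc_idx = {ln: wga_blocks.AnchorIndex(
                    {c: revcomp(s) for c, s in self.panel.seqs[ln].items()})
                    for ln in self.lines}
            sets = {}
            for a, b in itertools.combinations(self.lines, 2):
                raw = wga_blocks.align_pair(
                    self.panel.seqs[a], self.panel.seqs[b], a, b,
                    both_strands=self.both_strands,
                    index_a=idx[a], index_b=idx[b],
                    index_b_rc=rc_idx.get(b))
                sets[(a, b)] = wga_blocks.select_sabs(raw)
            self._cache["sab_sets"] = sets
        return self._cache["sab_sets"]

    @property
    def mab_sets(self):
        if "mab_sets" not in self._cache:
            self._cache["mab_sets"] = {
                pair: wga_blocks.chain_mabs(sabs)
                for pair, sabs in self.sab_sets.items()}
        return self._cache["mab_sets"]

    @property
    def partitions(self):
        if "partitions" not in self._cache:
            parts = {}
            for ln in self.lines:
                prof = wga_blocks.project_coverage(
                    ln, self.sab_sets, self.panel.group_of,
                    self.panel.chrom_lengths(ln))
                parts[ln] = wga_blocks.classify_partition(prof, self.core_k)
            self._cache["partitions"] = parts
        return self._cache["partitions"]

    # -- SNPs ----------------------------------------------------------------

    @property
    def core_blocks(self):
        if "core_blocks" not in self._cache:
            self._cache["core_blocks"] = core_snps.reproject_core(
                self.reference, self.partitions[self.reference], self.sab_sets)
        return self._cache["core_blocks"]

    @property
    def snp_matrix(self):
        if "snp_matrix" not in self._cache:
            self._cache["snp_matrix"] = core_snps.build_snp_matrix(
                self.panel, self.core_blocks)
        return self._cache["snp_matrix"]

    # -- haplotypes ----------------------------------------------------------

    @property
    def pairwise_runs(self):
        if "pairwise_runs" not in self._cache:
            runs = {}
            for pair in haplotypes.pair_order(self.snp_matrix.lines):
                runs[pair] = haplotypes.find_pairwise_runs(
                    self.snp_matrix, pair, seed_min=self.seed_min,
                    min_identity=self.min_identity)
            self._cache["pairwise_runs"] = runs
        return self._cache["pairwise_runs"]

    @property
    def higher_order(self):
        if "higher_order" not in self._cache:
            bits = haplotypes.binarize(self.snp_matrix, self.pairwise_runs)
            self._cache["higher_order"] = haplotypes.find_higher_order(
                bits, self.snp_matrix, seed_min=self.seed_min)
        return self._cache["higher_order"]

    # -- fl-LTR sharing ------------------------------------------------------

    @property
    def ltr_elements(self):
        if "ltr_elements" not in self._cache:
            if self.truth is None:
                raise InputError("fl-LTR elements require a truth set or "
                                 "explicit annotation input")
            elements = ltr_synteny.elements_from_truth(self.truth)
            self._cache["ltr_elements"] = ltr_synteny.filter_candidates(elements)
        return self._cache["ltr_elements"]

    @property
    def ltr_ages(self):
        if "ltr_ages" not in self._cache:
            ages = {}
            for el in self.ltr_elements:
                arr = self.panel.seqs[el.line][el.chrom]
                ages[el.element_id] = ltr_synteny.estimate_insertion_age(
                    arr[el.ltr5[0]:el.ltr5[1]], arr[el.ltr3[0]:el.ltr3[1]])
            self._cache["ltr_ages"] = ages
        return self._cache["ltr_ages"]

    @property
    def junction_clusters(self):
        if "junction_clusters" not in self._cache:
            sigs = []
            skipped = []
            for el in self.ltr_elements:
                pair = ltr_synteny.extract_junctions(el, self.panel.seqs[el.line])
                if pair is None:
                    skipped.append(el.element_id)
                    continue
                sigs.extend(pair)
            self._cache["junction_skipped"] = skipped
            self._cache["junction_clusters"] = ltr_synteny.cluster_junctions(sigs)
        return self._cache["junction_clusters"]

    @property
    def sharing_records(self):
        if "sharing_records" not in self._cache:
            self._cache["sharing_records"] = ltr_synteny.build_sharing(
                self.junction_clusters, self.ltr_elements, ages=self.ltr_ages)
        return self._cache["sharing_records"]

    # -- pan-genes -----------------------------------------------------------

    @property
    def gene_table(self) -> pd.DataFrame:
        if "gene_table" not in self._cache:
            if self.truth is None:
                raise InputError("gene models require a truth set or GFF3 input")
            self._cache["gene_table"] = self.truth.gene_loci.rename(
                columns={})[["line", "gene_id", "chrom", "start", "end",
                             "strand"]]
        return self._cache["gene_table"]

    @property
    def gene_clusters(self):
        if "gene_clusters" not in self._cache:
            from .synthetic_panel import gene_score_table
            scores = gene_score_table(self.panel, self.truth)
            rbh = pangene.reciprocal_best_hits(scores)
            self._cache["gene_clusters"] = pangene.build_clusters(
                rbh, self.gene_table)
        return self._cache["gene_clusters"]

    @property
    def pav_labels(self):
        if "pav_labels" not in self._cache:
            labels, hist = pangene.classify_pav(self.gene_clusters,
                                                len(self.lines))
            self._cache["pav_labels"] = labels
            self._cache["pav_hist"] = hist
        return self._cache["pav_labels"]

    @property
    def pav_hist(self):
        self.pav_labels
        return self._cache["pav_hist"]
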