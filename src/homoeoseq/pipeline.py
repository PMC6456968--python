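"""End-to-end orchestration of the synthetic-panel pipeline.

Wires the stages together in memory: simulate -> per-variety calling ->
genotype matrix and SNP taxonomy -> phasing of constitutive heterozygous
sites in a focal variety -> homoeolog sequence editing -> double-reference
read assignment -> pseudo-replicate counts -> differential expression.

Phasing deliberately uses only the positions the 13-variety taxonomy
classifies as inter-homoeolog: those are the constitutive A/B differences,
so the edited double reference discriminates subgenomes for every variety
(a varietal hemi-SNP of the focal variety would phase cleanly but would
misdirect reads of non-carrier varieties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import caller, expression, phasing, taxonomy
from .config import PipelineConfig
from .simulate import SimulatedDataset, merge_readsets

log = logging.getLogger("homoeoseq")


@dataclass
class PhaseStageResult:
    focal_variety: str
    blocks: dict[str, list[phasing.PhaseBlock]]
    seqsets: dict[str, phasing.HomoeologSequenceSet]
    n_blocks_total: int = 0
    n_blocks_retained: int = 0


def reference_codes(data: SimulatedDataset) -> dict[str, np.ndarray]:
    return {g.name: g.ref for g in data.genes.values()}


def call_all_varieties(data: SimulatedDataset, config: PipelineConfig | None = None
                       ) -> dict[str, caller.CallSet]:
    """Per-variety calling on the tissue-merged read sets."""
    config = config or PipelineConfig()
    ref = reference_codes(data)
    callsets = {}
    for variety in data.varieties:
        merged = merge_readsets([data.reads(variety, t) for t in data.params.tissues])
        callsets[variety] = caller.call_variants(merged, ref, config.caller)
        log.info("called variety %s", variety)
    return callsets


def classify_panel(data: SimulatedDataset, callsets: dict[str, caller.CallSet],
                   config: PipelineConfig | None = None) -> pd.DataFrame:
    config = config or PipelineConfig()
    matrix = taxonomy.build_genotype_matrix(callsets, reference_codes(data), config.taxonomy)
    return taxonomy.classify_matrix(matrix, config.taxonomy)


def phase_panel(data: SimulatedDataset, callsets: dict[str, caller.CallSet],
                classified: pd.DataFrame, config: PipelineConfig | None = None,
                focal_variety: str | None = None) -> PhaseStageResult:
    """Phase the focal variety's reads over constitutive heterozygous sites."""
    config = config or PipelineConfig()
    if focal_variety is None:
        focal_variety = "Svevo" if "Svevo" in data.varieties else data.varieties[0]
    focal = callsets[focal_variety]
    focal_reads = merge_readsets([data.reads(focal_variety, t) for t in data.params.tissues])
    inter = classified[classified["snp_class"] == "INTER_HOMOEOLOG"]

    result = PhaseStageResult(focal_variety=focal_variety, blocks={}, seqsets={})
    for gene, truth in data.genes.items():
        if gene in inter.index.get_level_values("transcript"):
            positions = np.asarray(sorted(inter.loc[gene].index), dtype=np.int64)
            het = positions[focal.genotype[gene][positions] == caller.Genotype.HET]
        else:
            het = np.empty(0, dtype=np.int64)
        ref_codes = truth.ref
        alt_codes = focal.alt[gene]
        fixed = np.flatnonzero(focal.genotype[gene] == caller.Genotype.HOM_ALT)
        gr = focal_reads.genes.get(gene)
        blocks: list[phasing.PhaseBlock] = []
        if het.size >= 2 and gr is not None and gr.n_reads:
            fragments, components = phasing.build_fragments(
                gr, het, ref_codes[het], alt_codes[het])
            for block_id, comp in enumerate(components, start=1):
                hap, mec = phasing.phase_block(fragments, comp, config.phasing)
                block = phasing.PhaseBlock(
                    transcript=gene, block_id=block_id,
                    site_positions=het[comp],
                    ref_alleles=ref_codes[het][comp],
                    alt_alleles=alt_codes[het][comp],
                    haplotype=hap, mec=mec,
                    n_fragments=sum(1 for f in fragments
                                    if int(f.sites[0]) in set(comp.tolist())),
                )
                result.n_blocks_total += 1
                kept = phasing.filter_and_label(block, config.phasing)
                if kept is not None:
                    blocks.append(kept)
                    result.n_blocks_retained += 1
        result.blocks[gene] = blocks
        result.seqsets[gene] = phasing.edit_homoeolog_sequences(
            gene, ref_codes, blocks,
            fixed_sites=fixed, fixed_alts=alt_codes[fixed])
    log.info("phasing: %d/%d blocks retained (focal %s)",
             result.n_blocks_retained, result.n_blocks_total, focal_variety)
    return result


def count_panel(data: SimulatedDataset, phase_result: PhaseStageResult) -> pd.DataFrame:
    """Homoeolog-specific pair counts for every (variety, tissue) sample."""
    seqsets = {g: s for g, s in phase_result.seqsets.items() if s.records}
    columns = []
    for variety in data.varieties:
        for tissue in data.params.tissues:
            columns.append(expression.assign_reads(data.reads(variety, tissue), seqsets))
    counts = pd.concat(columns, axis=1).fillna(0).astype(np.int64)
    return counts.sort_index()


def run_de(merged_counts: pd.DataFrame, config: PipelineConfig | None = None):
    """GLM Wald + per-tissue exact tests + multi-block concordance."""
    config = config or PipelineConfig()
    sf = expression.size_factors(merged_counts)
    tissue_of_col = np.array([t for t, _ in merged_counts.columns])
    alpha, trend, _ = expression.estimate_dispersion(merged_counts, sf, tissue_of_col)
    disp = pd.Series(alpha, index=merged_counts.index)
    glm = expression.glm_wald_test(merged_counts, config.de, sf, disp)
    tissue_results = pd.concat([
        expression.tissue_nb_test(merged_counts, t, config.de, sf, disp)
        for t in pd.unique(tissue_of_col)
    ], ignore_index=True)
    concordance = expression.block_concordance(glm)
    return glm, tissue_results, concordance, trend
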