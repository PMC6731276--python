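"""End-to-end discovery convenience: signatures -> enrichment -> composite
integration -> cross-omics threshold scan -> candidates -> pruning."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import OmicsMatrix, PathwayCollection, SiteGeneMap
from .gsea import CompositePathwaySignature, composite_integration, enrich_collection
from .integration import (
    CandidatePathwaySet,
    ThresholdScanResult,
    candidate_pathways,
    prune_redundant,
    threshold_scan,
    DEFAULT_GRID,
)
from .signatures import RankedSignature, ResponseGroups, methylation_signature, welch_signature


@dataclass
class DiscoveryResult:
    expr_signature: RankedSignature
    meth_signature: RankedSignature
    expr_composite: CompositePathwaySignature
    meth_composite: CompositePathwaySignature
    scan: ThresholdScanResult
    candidates: CandidatePathwaySet
    pruned: CandidatePathwaySet


def composite_enrichment(
    signature: RankedSignature,
    collection: PathwayCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> CompositePathwaySignature:
    """Signed + absolute-valued enrichment of a collection, integrated by
    the min-p rule."""
    signed, _ = enrich_collection(signature, collection, "signed", n_perm, seed)
    absolute, _ = enrich_collection(
        signature, collection, "absolute", n_perm, seed + 1
    )
    return composite_integration(signed, absolute)


def run_discovery(
    expression: OmicsMatrix,
    methylation: OmicsMatrix,
    sg_map: SiteGeneMap,
    groups: ResponseGroups,
    collection: PathwayCollection,
    n_perm: int = 1000,
    scan_runs: int = 100,
    scan_grid=DEFAULT_GRID,
    meth_mode: str = "one_site_per_gene",
    seed: int = 0,
) -> DiscoveryResult:
    """Run the full dual-omics pathway discovery on one cohort."""
    ss = np.random.SeedSequence(seed).generate_state(6) % (2**31)
    expr_sig = welch_signature(expression, groups)
    meth_sig = methylation_signature(methylation, sg_map, groups, mode=meth_mode)

    expr_comp = composite_enrichment(expr_sig, collection, n_perm, int(ss[0]))
    meth_comp = composite_enrichment(meth_sig, collection, n_perm, int(ss[1]))

    scan = threshold_scan(
        expr_comp, meth_comp, grid=scan_grid, runs=scan_runs, n_perm=n_perm,
        seed=int(ss[2]),
    )
    cands = candidate_pathways(
        scan, expr_comp, meth_comp, n_perm=n_perm, seed=int(ss[3])
    )
    pruned, _ = prune_redundant(cands, signature_genes=set(expr_sig.genes))
    return DiscoveryResult(
        expr_sig, meth_sig, expr_comp, meth_comp, scan, cands, pruned
    )
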