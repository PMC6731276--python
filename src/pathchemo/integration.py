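"""Cross-omics pathway integration: find pathways altered on both levels.

The composite expression pathway signature (pathways ranked by |NES|)
serves as the reference of a second-order GSEA whose "gene set" is the set
of pathways significant in the composite methylation signature.  The
methylation p-value threshold defining that query set is scanned over a
grid, with the enrichment repeated several times per threshold (the
permutation p/NES is stochastic) and the threshold with the highest mean
NES selected.  The leading-edge pathways of the enrichment at the optimal
threshold are the dual-level candidates; parent-child redundancy among
them is pruned by pairwise Fisher exact tests on leading-edge gene
overlaps with BH correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gsea import CompositePathwaySignature, EnrichmentResult, nes_pvalue
from .signatures import RankedSignature

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(np.round(np.arange(0.001, 0.0501, 0.005), 3))


def rank_by_abs_nes(composite: CompositePathwaySignature) -> list[str]:
    """Pathways ordered by descending |composite NES|; ties break to the
    smaller composite p, then name."""
    if len(composite) == 0:
        raise ValueError("empty composite signature")
    df = composite.table.assign(_abs=lambda d: d["composite_nes"].abs())
    df = df.sort_index(kind="stable").sort_values(
        by=["_abs", "composite_p"], ascending=[False, True], kind="stable"
    )
    return list(df.index)


def _reference_signature(composite: CompositePathwaySignature) -> RankedSignature:
    order = rank_by_abs_nes(composite)
    scores = composite.table.loc[order, "composite_nes"].abs()
    return RankedSignature(pd.Series(scores.to_numpy(), index=order), "abs_nes")


def pathway_gsea(
    reference: CompositePathwaySignature,
    query: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Second-order enrichment: items are pathways, scores are |composite
    NES| of the reference, nulls permute pathway labels."""
    if not query:
        raise ValueError("empty query pathway set")
    universe = set(reference.pathways)
    outside = query - universe
    if outside:
        raise ValueError(f"query pathways outside reference universe: {sorted(outside)[:5]}")
    sig = _reference_signature(reference)
    return nes_pvalue(
        sig, frozenset(query), n_perm=n_perm, seed=seed, pathway="pathway_query"
    )


@dataclass
class ThresholdScanResult:
    grid: list[float]
    mean_nes: pd.Series  # indexed by threshold; NaN where query empty
    n_query: pd.Series
    optimal: float
    runs_per_threshold: int


def threshold_scan(
    expr_composite: CompositePathwaySignature,
    meth_composite: CompositePathwaySignature,
    grid: tuple[float, ...] = DEFAULT_GRID,
    runs: int = 100,
    n_perm: int = 1000,
    seed: int = 0,
) -> ThresholdScanResult:
    """Scan the methylation-p threshold defining the query pathway set.

    For each threshold the pathway-level GSEA is repeated ``runs`` times
    under a deterministic seed sequence derived from ``seed`` and the mean
    NES recorded; the optimal threshold maximizes mean NES (ties to the
    smallest threshold).
    """
    if any(t <= 0 or t > 0.05 for t in grid):
        raise ValueError("thresholds must lie in (0, 0.05]")
    universe = set(expr_composite.pathways)
    meth = meth_composite.table
    child_seeds = np.random.SeedSequence(seed).generate_state(runs) % (2**31)

    mean_nes, n_query = {}, {}
    for theta in grid:
        query = set(meth.index[meth["composite_p"] <= theta]) & universe
        n_query[theta] = len(query)
        if not query:
            mean_nes[theta] = np.nan
            continue
        nes_vals = [
            pathway_gsea(expr_composite, query, n_perm=n_perm, seed=int(s)).nes
            for s in child_seeds
        ]
        mean_nes[theta] = float(np.mean(nes_vals))
    mean_s = pd.Series(mean_nes)
    if mean_s.isna().all():
        raise ValueError("query set empty at every threshold")
    optimal = float(mean_s.idxmax())  # idxmax returns first (smallest) on ties
    return ThresholdScanResult(list(grid), mean_s, pd.Series(n_query), optimal, runs)


@dataclass
class CandidatePathwaySet:
    """Dual-level candidate pathways with their tagged leading-edge genes.

    ``table``: per-pathway composite NES/p from both omics levels, indexed
    by pathway.  ``gene_tags``: pathway -> {gene: expression|methylation|both}
    built from the union of the two leading edges.  ``enrichment`` is the
    pathway-level GSEA result that produced the set.
    """

    table: pd.DataFrame
    gene_tags: dict[str, dict[str, str]]
    enrichment: EnrichmentResult
    no_dual_signal: bool = False

    @property
    def pathways(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def leading_edge_genes(self, pathway: str) -> list[str]:
        return sorted(self.gene_tags[pathway])

    def to_frame(self) -> pd.DataFrame:
        tags = pd.Series(
            {
                p: ";".join(f"{g}:{t}" for g, t in sorted(self.gene_tags[p].items()))
                for p in self.pathways
            },
            name="leading_edge",
        )
        return self.table.join(tags)


def candidate_pathways(
    scan: ThresholdScanResult,
    expr_composite: CompositePathwaySignature,
    meth_composite: CompositePathwaySignature,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CandidatePathwaySet:
    """Pathway-level GSEA at the optimal threshold; candidates are the
    leading-edge pathways, each annotated with its expression and
    methylation leading-edge genes tagged by level."""
    meth = meth_composite.table
    query = set(meth.index[meth["composite_p"] <= scan.optimal]) & set(
        expr_composite.pathways
    )
    enr = pathway_gsea(expr_composite, query, n_perm=n_perm, seed=seed)
    if not enr.leading_edge:
        raise ValueError("pathway-level enrichment has an empty leading edge")
    no_signal = enr.p > alpha
    if no_signal:
        logger.warning(
            "pathway-level enrichment p=%.3g > %.2f: no dual-level signal",
            enr.p, alpha,
        )
    rows, tags = [], {}
    for name in enr.leading_edge:
        e_edge = set(expr_composite.leading_edges.get(name, []))
        m_edge = set(meth_composite.leading_edges.get(name, []))
        tags[name] = {
            g: ("both" if g in e_edge and g in m_edge
                else "expression" if g in e_edge else "methylation")
            for g in e_edge | m_edge
        }
        rows.append(
            {
                "pathway": name,
                "expr_nes": expr_composite.table.loc[name, "composite_nes"],
                "expr_p": expr_composite.table.loc[name, "composite_p"],
                "meth_nes": meth.loc[name, "composite_nes"],
                "meth_p": meth.loc[name, "composite_p"],
            }
        )
    table = pd.DataFrame(rows).set_index("pathway")
    return CandidatePathwaySet(table, tags, enr, no_dual_signal=no_signal)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def pairwise_overlap_tests(
    candidates: CandidatePathwaySet, universe_size: int
) -> pd.DataFrame:
    """Two-sided Fisher exact test of leading-edge gene overlap for every
    pathway pair, with BH-corrected q-values."""
    names = candidates.pathways
    edges = {p: set(candidates.gene_tags[p]) for p in names}
    rows = []
    for a, b in itertools.combinations(names, 2):
        ea, eb = edges[a], edges[b]
        n11 = len(ea & eb)
        n10 = len(ea - eb)
        n01 = len(eb - ea)
        n00 = universe_size - n11 - n10 - n01
        if n00 < 0:
            raise ValueError("universe smaller than union of leading edges")
        p = float(stats.fisher_exact([[n11, n10], [n01, n00]])[1])
        expected = len(ea) * len(eb) / universe_size
        rows.append(
            {"a": a, "b": b, "overlap": n11, "expected": expected, "p": p}
        )
    df = pd.DataFrame(
        rows, columns=["a", "b", "overlap", "expected", "p"]
    )
    df["q"] = (
        stats.false_discovery_control(df["p"].to_numpy(), method="bh")
        if len(df) else np.empty(0)
    )
    return df


def prune_redundant(
    candidates: CandidatePathwaySet,
    universe_size: int | None = None,
    signature_genes: set[str] | None = None,
    q_cut: float = 0.05,
    representative_p: str = "expression",
) -> tuple[CandidatePathwaySet, pd.DataFrame]:
    """Collapse parent-child pathway redundancy.

    Pairs whose leading-edge overlap is significantly *over*-represented
    (BH q < ``q_cut`` and observed overlap above its expectation under
    independence — the two-sided test would otherwise also flag depleted
    overlaps) are joined into connected components; each component keeps
    the single pathway whose composite p (expression by default, or min
    over both omics) is lowest.  The gene universe defaults to the union
    of candidate leading edges and ``signature_genes`` when given.
    Returns the pruned set and the pairwise test table.
    """
    if len(candidates) == 0:
        raise ValueError("no candidates to prune")
    if universe_size is None:
        edge_union = set().union(*(
            set(candidates.gene_tags[p]) for p in candidates.pathways
        ))
        universe_size = len(edge_union | (signature_genes or set()))
    tests = pairwise_overlap_tests(candidates, universe_size)

    uf = _UnionFind(candidates.pathways)
    for _, row in tests.iterrows():
        if row["q"] < q_cut and row["overlap"] > row["expected"]:
            uf.union(row["a"], row["b"])

    if representative_p == "expression":
        crit = candidates.table["expr_p"]
    elif representative_p == "min":
        crit = candidates.table[["expr_p", "meth_p"]].min(axis=1)
    else:
        raise ValueError(f"unknown representative_p {representative_p!r}")

    components: dict[str, list[str]] = {}
    for p in candidates.pathways:
        components.setdefault(uf.find(p), []).append(p)
    keep = []
    for members in components.values():
        keep.append(min(members, key=lambda m: (crit.loc[m], m)))
    keep = [p for p in candidates.pathways if p in set(keep)]
    pruned = CandidatePathwaySet(
        candidates.table.loc[keep],
        {p: candidates.gene_tags[p] for p in keep},
        candidates.enrichment,
        candidates.no_dual_signal,
    )
    return pruned, tests
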