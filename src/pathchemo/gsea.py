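"""Weighted running-sum gene set enrichment with permutation NES/p.

The statistic is the classic weighted Kolmogorov-Smirnov running sum:
walking down the ranked signature, members of the query set add
|score|^weight / sum(|hit score|^weight) and non-members subtract
1/(N - N_hits); the enrichment score (ES) is the extremum of the running
sum.  Nulls come from permuting gene labels — equivalently, placing the
hit set at random ranks — with NES normalized by the mean same-sign null
ES and an add-one empirical p conditioned on the sign.

Two modes are supported: *signed* enrichment on the raw differential
scores (direction-aware) and *absolute-valued* enrichment on |scores|,
which detects sets whose genes move in both directions.  The composite
integration keeps, per pathway, whichever mode has the smaller p, never
considering absolute-mode results with negative NES (those reflect
enrichment in the unchanged middle of the signature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import PathwayCollection
from .signatures import RankedSignature

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    pathway: str
    es: float
    nes: float
    p: float
    leading_edge: list[str]
    mode: str  # signed | absolute
    n_perm: int

    def __post_init__(self) -> None:
        if self.es != 0 and self.nes != 0 and np.sign(self.nes) != np.sign(self.es):
            raise ValueError("NES sign must match ES sign")


# ---------------------------------------------------------------------------
# running sum


def _hit_weights(scores: np.ndarray, weight_exp: float) -> np.ndarray:
    return np.abs(scores) ** weight_exp


def enrichment_score(
    signature: RankedSignature,
    gene_set: set[str] | frozenset[str],
    weight_exp: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """ES, full running sum, and leading edge for one gene set.

    The leading edge is the hit genes at or before the running-sum peak for
    positive ES, and at or after the trough for negative ES.
    """
    genes = signature.genes
    if len(genes) < 2:
        raise ValueError("signature must contain >=2 genes")
    hit = np.fromiter((g in gene_set for g in genes), bool, count=len(genes))
    k = int(hit.sum())
    if k == 0:
        raise ValueError("gene set does not intersect the signature")
    scores = signature.scores.to_numpy(dtype=float)
    w = _hit_weights(scores, weight_exp)
    nr = w[hit].sum()
    if nr == 0:
        raise ValueError("all hit scores are zero; weighting undefined")

    n_miss = len(genes) - k
    steps = np.where(hit, w / nr, -1.0 / n_miss if n_miss else 0.0)
    running = np.cumsum(steps)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es, peak = float(running[i_max]), i_max
        edge = [g for g, h in zip(genes[: peak + 1], hit[: peak + 1]) if h]
    else:
        es, peak = float(running[i_min]), i_min
        edge = [g for g, h in zip(genes[peak + 1 :], hit[peak + 1 :]) if h]
    return es, running, edge


def _null_es(
    w_all: np.ndarray, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES for a set of size k placed at random ranks, vectorized.

    Between hits the running sum only falls, so the maximum is attained at a
    hit position and the minimum just before a hit (or at the boundary);
    both are computed in O(k) per permutation from sorted hit positions.
    """
    n = len(w_all)
    if k >= n:
        return np.ones(n_perm)
    pos = np.argpartition(rng.random((n_perm, n)), k - 1, axis=1)[:, :k]
    pos.sort(axis=1)
    w = w_all[pos]
    nr = w.sum(axis=1, keepdims=True)
    # a null draw of all-zero weights degenerates to uniform steps
    w = np.where(nr > 0, w / np.where(nr == 0, 1.0, nr), 1.0 / k)
    cum = np.cumsum(w, axis=1)
    j = np.arange(1, k + 1)
    m = n - k
    at_hit = cum - (pos + 1 - j) / m
    pre_hit = np.concatenate(
        [np.zeros((n_perm, 1)), cum[:, :-1]], axis=1
    ) - (pos - j + 1) / m
    hi = np.maximum(at_hit.max(axis=1), 0.0)
    lo = np.minimum(pre_hit.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def nes_pvalue(
    signature: RankedSignature,
    gene_set: set[str] | frozenset[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exp: float = 1.0,
    mode: str = "signed",
    pathway: str = "",
    _null: np.ndarray | None = None,
) -> EnrichmentResult:
    """Permutation-normalized enrichment for one gene set.

    NES = ES / |mean of same-sign null ES|;
    p = (#{same-sign nulls with |ES_null| >= |ES|} + 1) / (#same-sign + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    es, _, edge = enrichment_score(signature, gene_set, weight_exp)
    if _null is None:
        genes = set(signature.genes)
        k = len(genes & set(gene_set))
        w_all = _hit_weights(signature.scores.to_numpy(dtype=float), weight_exp)
        _null = _null_es(w_all, k, n_perm, np.random.default_rng(seed))
    same = _null[_null > 0] if es >= 0 else _null[_null < 0]
    if len(same) == 0:
        logger.warning(
            "no matching-sign null draws for %s; p floored", pathway or "set"
        )
        denom = np.abs(_null).mean() or 1.0
        return EnrichmentResult(
            pathway, es, es / denom, 1.0 / (n_perm + 1), edge, mode, n_perm
        )
    nes = es / abs(same.mean())
    p = (int((np.abs(same) >= abs(es)).sum()) + 1) / (len(same) + 1)
    return EnrichmentResult(pathway, es, float(nes), float(p), edge, mode, n_perm)


def absolute_signature(signature: RankedSignature) -> RankedSignature:
    """Collapse the two signature tails: scores replaced by absolute values
    and re-sorted descending (ties keep the original rank order)."""
    return RankedSignature(
        signature.scores.abs(), signature.method, signature.site_to_gene
    )


def _map_sites_to_genes(signature: RankedSignature) -> RankedSignature:
    """For an all-sites signature, keep per gene the site with the largest
    |score| and re-key by gene so pathway gene sets apply."""
    stg = signature.site_to_gene
    df = pd.DataFrame(
        {"gene": stg.reindex(signature.scores.index), "score": signature.scores}
    ).dropna(subset=["gene"])
    best = df.loc[df["score"].abs().groupby(df["gene"]).idxmax()]
    return RankedSignature(
        pd.Series(best["score"].to_numpy(), index=best["gene"]), signature.method
    )


def enrich_collection(
    signature: RankedSignature,
    collection: PathwayCollection,
    mode: str = "signed",
    n_perm: int = 1000,
    seed: int = 0,
    weight_exp: float = 1.0,
) -> tuple[list[EnrichmentResult], list[str]]:
    """Enrichment of every pathway in a collection against one signature.

    Returns (results, skipped): pathways with no signature overlap are
    skipped.  In absolute mode the signature is |score|-resorted first;
    negative-NES absolute results are retained in the output but are
    ineligible for composite integration.  Null permutations are shared
    across pathways with the same overlap size, seeded deterministically.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    work = signature
    if work.site_to_gene is not None:
        work = _map_sites_to_genes(work)
    if mode == "absolute":
        work = absolute_signature(work)

    sig_genes = set(work.genes)
    w_all = _hit_weights(work.scores.to_numpy(dtype=float), weight_exp)
    null_cache: dict[int, np.ndarray] = {}
    rng = np.random.default_rng(seed)

    results, skipped = [], []
    for pw in collection:
        k = len(pw.genes & sig_genes)
        if k == 0:
            skipped.append(pw.name)
            continue
        if k not in null_cache:
            null_cache[k] = _null_es(w_all, k, n_perm, rng)
        results.append(
            nes_pvalue(
                work, pw.genes, n_perm=n_perm, seed=seed, weight_exp=weight_exp,
                mode=mode, pathway=pw.name, _null=null_cache[k],
            )
        )
    if skipped:
        logger.info("%d pathways skipped (no signature overlap)", len(skipped))
    return results, skipped


@dataclass
class CompositePathwaySignature:
    """Per-pathway integrated enrichment: whichever of the signed and
    positive-NES absolute results has the lower p, rankable by |NES|.

    ``table`` columns: composite_nes, composite_p, source_mode, signed_nes,
    signed_p, abs_nes, abs_p; indexed by pathway name.  ``leading_edges``
    maps pathway -> leading-edge gene list of the chosen mode.
    """

    table: pd.DataFrame
    leading_edges: dict[str, list[str]] = field(default_factory=dict)

    @property
    def pathways(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def composite_integration(
    signed: list[EnrichmentResult],
    absolute: list[EnrichmentResult],
) -> CompositePathwaySignature:
    """Integrate signed and absolute-valued enrichment by the min-p rule.

    Absolute results with NES <= 0 are excluded; at equal p the signed
    result wins (directional information retained).  Pathways with no
    eligible result are dropped with a warning.
    """
    s_by = {r.pathway: r for r in signed}
    a_by = {r.pathway: r for r in absolute}
    rows, edges = [], {}
    for name in sorted(set(s_by) | set(a_by)):
        s, a = s_by.get(name), a_by.get(name)
        a_ok = a is not None and a.nes > 0
        if s is None and not a_ok:
            logger.warning("pathway %s has no eligible enrichment; dropped", name)
            continue
        if s is not None and (not a_ok or s.p <= a.p):
            chosen = s
        else:
            chosen = a
        rows.append(
            {
                "pathway": name,
                "composite_nes": chosen.nes,
                "composite_p": chosen.p,
                "source_mode": chosen.mode,
                "signed_nes": s.nes if s else np.nan,
                "signed_p": s.p if s else np.nan,
                "abs_nes": a.nes if a else np.nan,
                "abs_p": a.p if a else np.nan,
            }
        )
        edges[name] = list(chosen.leading_edge)
    if not rows:
        raise ValueError("no pathway with an eligible enrichment result")
    return CompositePathwaySignature(
        pd.DataFrame(rows).set_index("pathway"), edges
    )


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p for r in results],
            "mode": [r.mode for r in results],
            "leading_edge": [";".join(r.leading_edge) for r in results],
        }
    ).set_index("pathway")
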