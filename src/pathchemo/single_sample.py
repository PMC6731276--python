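"""Per-sample pathway activity by single-sample enrichment.

Each sample's z-scored profile (z-scored per gene or site across the
cohort) is itself a ranked signature; running signed and absolute-valued
enrichment of each candidate pathway against it and integrating by the
min-p rule yields a pathway x sample activity matrix of composite NES
values.  Expression and methylation activities use the identical code
path — the omics level is just the input matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import OmicsMatrix
from .gsea import composite_integration, nes_pvalue, _hit_weights, _null_es, absolute_signature
from .signatures import RankedSignature

logger = logging.getLogger(__name__)


@dataclass
class ActivityMatrix:
    """Pathway x sample composite NES values with per-cell source mode."""

    values: pd.DataFrame  # pathways x samples
    source_mode: pd.DataFrame  # same shape, entries signed|absolute
    level: str  # expression | methylation

    @property
    def pathways(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def zscore_rows(matrix: OmicsMatrix) -> OmicsMatrix:
    """Per-feature standardization across samples ((x - mean) / sd, sample
    sd with n-1 denominator).  Constant features are dropped with a
    warning."""
    if matrix.shape[1] < 2:
        raise ValueError("z-scoring requires >=2 samples")
    vals = matrix.values
    sd = vals.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant features dropped before z-scoring",
                       int(constant.sum()))
        vals = vals.loc[~constant]
        sd = sd.loc[~constant]
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return OmicsMatrix(z, matrix.space)


def sample_activity(
    zscored: OmicsMatrix,
    pathways,  # CandidatePathwaySet or PathwayCollection-like with names+gene sets
    n_perm: int = 1000,
    seed: int = 0,
    level: str = "expression",
    modes: tuple[str, ...] = ("signed", "absolute"),
) -> ActivityMatrix:
    """Composite single-sample enrichment of each pathway in each sample.

    ``pathways`` may be a CandidatePathwaySet (gene sets = tagged leading
    edges) or any object with ``.names``/iterable of (name, genes).  Cells
    are composite NES under the min-p rule.  The same permutation draws are
    reused for every sample (as for gene sets in cohort-level GSEA), so
    identical profiles receive identical activities.
    """
    gene_sets = _as_gene_sets(pathways)
    features = set(zscored.feature_ids)
    usable = {n: gs & features for n, gs in gene_sets.items()}
    empty = [n for n, gs in usable.items() if not gs]
    for n in empty:
        logger.warning("pathway %s has no genes in the matrix; NaN activity", n)

    names = list(gene_sets)
    nes = pd.DataFrame(np.nan, index=names, columns=zscored.sample_ids)
    mode_df = pd.DataFrame("", index=names, columns=zscored.sample_ids)

    for sample in zscored.sample_ids:
        sig = RankedSignature(zscored.values[sample].copy(), "zscore")
        per_mode = {}
        for mode in modes:
            work = absolute_signature(sig) if mode == "absolute" else sig
            w_all = _hit_weights(work.scores.to_numpy(dtype=float), 1.0)
            rng = np.random.default_rng(seed + (0 if mode == "signed" else 1))
            cache: dict[int, np.ndarray] = {}
            res = []
            for name in names:
                gs = usable[name]
                if not gs:
                    continue
                k = len(gs)
                if k not in cache:
                    cache[k] = _null_es(w_all, k, n_perm, rng)
                res.append(
                    nes_pvalue(work, frozenset(gs), n_perm=n_perm, mode=mode,
                               pathway=name, _null=cache[k])
                )
            per_mode[mode] = res
        if len(modes) == 2:
            comp = composite_integration(per_mode["signed"], per_mode["absolute"])
        else:
            comp = composite_integration(
                per_mode.get("signed", []), per_mode.get("absolute", [])
            )
        nes.loc[comp.table.index, sample] = comp.table["composite_nes"]
        mode_df.loc[comp.table.index, sample] = comp.table["source_mode"]
    return ActivityMatrix(nes, mode_df, level)


def _as_gene_sets(pathways) -> dict[str, frozenset[str]]:
    # CandidatePathwaySet: use tagged leading-edge genes
    if hasattr(pathways, "gene_tags"):
        return {
            n: frozenset(pathways.gene_tags[n]) for n in pathways.pathways
        }
    # PathwayCollection
    if hasattr(pathways, "pathways") and hasattr(pathways, "names"):
        return {p.name: frozenset(p.genes) for p in pathways}
    if isinstance(pathways, dict):
        return {n: frozenset(g) for n, g in pathways.items()}
    raise TypeError("unsupported pathway container")
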