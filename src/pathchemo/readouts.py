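"""Read-out gene selection: one clinically measurable proxy per pathway.

Candidate genes are the leading-edge genes of each candidate pathway.
Evidence per gene combines (i) Pearson correlation of the gene's values
with the pathway's per-sample activity (NES) and (ii) a Cox
likelihood-ratio test of the gene against survival; the two p-values are
combined by Fisher's method and the gene with the smallest combined p is
selected per pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .data_io import ClinicalTable, OmicsMatrix
from .integration import CandidatePathwaySet
from .single_sample import ActivityMatrix

logger = logging.getLogger(__name__)


@dataclass
class ReadoutCandidate:
    gene: str
    pathway: str
    pearson_r: float
    p_corr: float
    p_lr: float
    p_combined: float
    level: str  # expression | methylation | both


def candidate_genes(candidates: CandidatePathwaySet, pathway: str) -> list[str]:
    """Union of the pathway's expression and methylation leading edges."""
    genes = candidates.gene_tags.get(pathway, {})
    if not genes:
        raise ValueError(f"pathway {pathway!r} has an empty leading edge")
    return sorted(genes)


def correlate_with_activity(
    gene_values: pd.Series, pathway_activity: pd.Series
) -> tuple[float, float]:
    """Pearson r between per-sample gene values and pathway activity, with
    the two-sided t-transform p (n-2 df)."""
    common = gene_values.index.intersection(pathway_activity.index)
    x = gene_values.loc[common].to_numpy(dtype=float)
    y = pathway_activity.loc[common].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cox_lr_gene(gene_values: pd.Series, clinical: ClinicalTable) -> float:
    """Likelihood-ratio p for a single continuous gene covariate in a Cox
    proportional-hazards model."""
    if gene_values.nunique() <= 1:
        raise ValueError("constant gene; Cox model undefined")
    clin = clinical.table.loc[list(gene_values.index)]
    df = pd.DataFrame(
        {
            "gene": gene_values.astype(float),
            "time": clin["time_to_event"].astype(float).clip(lower=1e-8),
            "event": clin["event"].astype(int),
        }
    )
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        logger.warning("Cox LR non-convergence for gene covariate: %s", err)
        return float("nan")
    return float(cph.log_likelihood_ratio_test().p_value)


def fisher_combine(pvalues: list[float]) -> tuple[float, float]:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square with 2k df."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    x = float(-2 * np.log(p).sum())
    return x, float(stats.chi2.sf(x, df=2 * len(p)))


def score_candidates(
    candidates: CandidatePathwaySet,
    expr: OmicsMatrix,
    activity: ActivityMatrix,
    clinical: ClinicalTable,
    meth_m: OmicsMatrix | None = None,
) -> list[ReadoutCandidate]:
    """Evaluate every leading-edge gene of every candidate pathway.

    Correlation and survival association use expression values for
    expression/both-tagged genes and M-values (if provided) for
    methylation-only genes; genes absent from the relevant matrix are
    skipped.
    """
    out: list[ReadoutCandidate] = []
    for pathway in candidates.pathways:
        act = activity.values.loc[pathway].dropna()
        for gene in candidate_genes(candidates, pathway):
            level = candidates.gene_tags[pathway][gene]
            source = expr if level in ("expression", "both") else (meth_m or expr)
            if gene not in source.values.index:
                continue
            vals = source.values.loc[gene, act.index]
            try:
                r, p_corr = correlate_with_activity(vals, act)
                p_lr = cox_lr_gene(vals, clinical)
            except ValueError as err:
                logger.info("skipping %s/%s: %s", pathway, gene, err)
                continue
            finite = [p for p in (p_corr, p_lr) if np.isfinite(p) and p > 0]
            p_comb = fisher_combine(finite)[1] if finite else float("nan")
            out.append(
                ReadoutCandidate(gene, pathway, r, p_corr, p_lr, p_comb, level)
            )
    return out


def select_readouts(
    scored: list[ReadoutCandidate],
) -> tuple[dict[str, ReadoutCandidate], list[str]]:
    """One read-out gene per pathway: smallest combined p, ties broken by
    larger |r| then gene name.  Pathways with no viable candidate are
    returned in the flagged list."""
    by_pathway: dict[str, list[ReadoutCandidate]] = {}
    for c in scored:
        by_pathway.setdefault(c.pathway, []).append(c)
    selected, flagged = {}, []
    for pathway, cands in by_pathway.items():
        viable = [c for c in cands if np.isfinite(c.p_combined)]
        if not viable:
            flagged.append(pathway)
            continue
        selected[pathway] = min(
            viable, key=lambda c: (c.p_combined, -abs(c.pearson_r), c.gene)
        )
    if flagged:
        logger.warning("pathways without viable read-out: %s", flagged)
    return selected, flagged


def readouts_frame(selected: dict[str, ReadoutCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": p,
                "gene": c.gene,
                "r": c.pearson_r,
                "p_corr": c.p_corr,
                "p_lr": c.p_lr,
                "p_combined": c.p_combined,
                "level": c.level,
            }
            for p, c in sorted(selected.items())
        ]
    )
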