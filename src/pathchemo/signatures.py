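"""Extreme-responder group definition and differential signatures.

Chemotherapy response groups follow an extreme-responder design: patients
with an event inside a short window after therapy start (default one year)
are *poor* responders; patients who stay event-free beyond a longer
follow-up (default two years) are *favorable*; everyone else is excluded.
Differential signatures are ranked gene (or CpG site) lists scored by the
two-sample two-tailed Welch t statistic or by the log-scale fold change,
always oriented poor minus favorable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (
    ClinicalTable,
    OmicsMatrix,
    SiteGeneMap,
    matrix_beta_to_m,
    select_site_per_gene,
)

logger = logging.getLogger(__name__)


@dataclass
class ResponseGroups:
    poor: set[str]
    favorable: set[str]
    excluded: set[str]
    thresholds: tuple[float, float]  # (poor_window days, favorable_min days)

    def __post_init__(self) -> None:
        if self.poor & self.favorable:
            raise ValueError("poor and favorable groups overlap")


@dataclass
class RankedSignature:
    """Genes (or sites) ordered by a differential score, highest first.

    ``scores`` is a pandas Series indexed by unique feature id, sorted
    descending; ties keep the order in which features entered.
    """

    scores: pd.Series
    method: str  # welch_t | fold_change | zscore | abs_nes
    site_to_gene: pd.Series | None = None  # only for all-sites signatures

    def __post_init__(self) -> None:
        s = self.scores
        if s.index.duplicated().any():
            raise ValueError("duplicate features in signature")
        if not np.isfinite(s.to_numpy(dtype=float)).all():
            raise ValueError("non-finite scores in signature")
        # stable sort: ties keep input order
        order = np.argsort(-s.to_numpy(dtype=float), kind="stable")
        self.scores = s.iloc[order]

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        return self.scores.rename("score").rename_axis("feature").reset_index()


def define_response_groups(
    clinical: ClinicalTable,
    therapy: str | None = None,
    poor_window: float = 365.0,
    favorable_min: float = 730.0,
) -> ResponseGroups:
    """Split a cohort into poor / favorable / excluded response groups.

    Poor: event within ``poor_window`` days.  Favorable: event-free with
    follow-up longer than ``favorable_min`` days.  Samples with an event in
    the gap, or censored with short follow-up, are excluded.  Rows are first
    restricted to the matching therapy with ``neoadjuvant == 0``.
    """
    df = clinical.table
    if therapy is not None:
        df = df[df["therapy"] == therapy]
    df = df[df["neoadjuvant"] == 0]
    if df.empty:
        raise ValueError(f"no adjuvant samples for therapy {therapy!r}")

    event = df["event"].astype(int)
    time = df["time_to_event"].astype(float)
    poor = set(df.loc[(event == 1) & (time <= poor_window), "sample_id"])
    favorable = set(df.loc[(event == 0) & (time > favorable_min), "sample_id"])
    excluded = set(df["sample_id"]) - poor - favorable
    if not poor or not favorable:
        raise ValueError(
            "empty response group (poor=%d, favorable=%d); review the "
            "poor_window/favorable_min thresholds" % (len(poor), len(favorable))
        )
    return ResponseGroups(poor, favorable, excluded, (poor_window, favorable_min))


def balance_check(
    groups: ResponseGroups,
    clinical: ClinicalTable,
    covariates: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare covariate distributions between the two response groups.

    Numeric covariates use a two-sided Welch t test; categorical ones a
    Fisher exact test (2x2) or chi-square contingency test for more levels.
    Covariates with p < ``alpha`` are flagged as imbalanced.
    """
    df = clinical.table
    rows = []
    for cov in covariates:
        if cov not in df.columns:
            raise KeyError(f"covariate {cov!r} not in clinical table")
        a = df.loc[df["sample_id"].isin(groups.poor), cov]
        b = df.loc[df["sample_id"].isin(groups.favorable), cov]
        note = ""
        if pd.api.types.is_numeric_dtype(df[cov]):
            test = "welch_t"
            if a.nunique() <= 1 and b.nunique() <= 1 and a.iloc[0] == b.iloc[0]:
                p, note = 1.0, "degenerate: covariate constant"
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
                if np.isnan(p):
                    p, note = 1.0, "degenerate: zero variance"
        else:
            levels = sorted(set(a) | set(b))
            tab = np.array(
                [[np.sum(a == lv) for lv in levels], [np.sum(b == lv) for lv in levels]]
            )
            if len(levels) <= 1:
                test, p, note = "fisher_exact", 1.0, "degenerate: single level"
            elif len(levels) == 2:
                test = "fisher_exact"
                p = float(stats.fisher_exact(tab.T)[1])
            else:
                test = "chi2"
                p = float(stats.chi2_contingency(tab.T)[1])
        rows.append(
            {"covariate": cov, "test": test, "p": p, "flagged": p < alpha, "note": note}
        )
    return pd.DataFrame(rows).set_index("covariate")


def _group_arrays(
    matrix: OmicsMatrix, groups: ResponseGroups
) -> tuple[np.ndarray, np.ndarray]:
    cols = set(matrix.sample_ids)
    poor = sorted(groups.poor & cols)
    fav = sorted(groups.favorable & cols)
    if len(poor) < 2 or len(fav) < 2:
        raise ValueError(
            f"each group needs >=2 matrix samples (poor={len(poor)}, "
            f"favorable={len(fav)})"
        )
    return (
        matrix.values[poor].to_numpy(dtype=float),
        matrix.values[fav].to_numpy(dtype=float),
    )


def welch_signature(matrix: OmicsMatrix, groups: ResponseGroups) -> RankedSignature:
    """Per-feature Welch t statistic, poor minus favorable orientation.

    Features with zero variance in both groups (t undefined) are dropped
    with a warning.
    """
    a, b = _group_arrays(matrix, groups)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    degenerate = (va == 0) & (vb == 0)
    if degenerate.any():
        logger.warning(
            "%d features constant in both groups dropped", int(degenerate.sum())
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(
            va / a.shape[1] + vb / b.shape[1]
        )
    keep = ~degenerate & np.isfinite(t)
    scores = pd.Series(t[keep], index=np.asarray(matrix.feature_ids)[keep])
    if scores.empty:
        raise ValueError("no feature with nonzero variance in either group")
    return RankedSignature(scores, "welch_t")


def foldchange_signature(
    matrix: OmicsMatrix, groups: ResponseGroups
) -> RankedSignature:
    """Mean difference poor minus favorable on already-log-scale values,
    i.e. a log2 fold change."""
    a, b = _group_arrays(matrix, groups)
    scores = pd.Series(
        a.mean(axis=1) - b.mean(axis=1), index=matrix.feature_ids
    )
    return RankedSignature(scores, "fold_change")


def methylation_signature(
    meth: OmicsMatrix,
    sg_map: SiteGeneMap,
    groups: ResponseGroups,
    mode: str = "one_site_per_gene",
    method: str = "welch_t",
) -> RankedSignature:
    """Differential methylation signature from a beta-value matrix.

    ``one_site_per_gene`` collapses to the highest-CV site per gene first
    (gene-keyed output); ``all_sites`` scores every site and carries the
    site-to-gene map so enrichment can translate sites to pathway genes.
    Welch t is computed on M-values (logit-2 of beta); fold change stays on
    the beta scale.
    """
    if meth.space != "beta":
        raise ValueError("methylation signature expects beta-space input")
    mapped_sites = set(sg_map.table["site_id"])
    if not mapped_sites & set(meth.feature_ids):
        raise ValueError("site-gene map and methylation matrix share no sites")

    if mode == "one_site_per_gene":
        collapsed, _ = select_site_per_gene(meth, sg_map)
        work, site_to_gene = collapsed, None
    elif mode == "all_sites":
        keep = [s for s in meth.feature_ids if s in mapped_sites]
        work = OmicsMatrix(meth.values.loc[keep], "beta")
        stg = (
            sg_map.table[sg_map.table["site_id"].isin(keep)]
            .drop_duplicates("site_id")
            .set_index("site_id")["gene"]
        )
        site_to_gene = stg
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if method == "welch_t":
        work = matrix_beta_to_m(work)
        sig = welch_signature(work, groups)
    elif method == "fold_change":
        sig = foldchange_signature(work, groups)
    else:
        raise ValueError(f"unknown method {method!r}")
    sig.site_to_gene = site_to_gene
    return sig


def greedy_rebalance(
    groups: ResponseGroups,
    clinical: ClinicalTable,
    covariates: list[str],
    alpha: float = 0.05,
    max_drop: int = 10,
    seed: int = 0,
) -> ResponseGroups:
    """Convenience stratified sub-sampler: greedily drop samples until no
    covariate is flagged by :func:`balance_check` or ``max_drop`` removals.

    Not part of the core discovery contract; callers decide whether to use
    the rebalanced groups.
    """
    rng = np.random.default_rng(seed)
    cur = ResponseGroups(
        set(groups.poor), set(groups.favorable), set(groups.excluded),
        groups.thresholds,
    )
    for _ in range(max_drop):
        report = balance_check(cur, clinical, covariates, alpha=alpha)
        if not report["flagged"].any():
            break
        larger = cur.poor if len(cur.poor) >= len(cur.favorable) else cur.favorable
        if len(larger) <= 2:
            break
        victim = rng.choice(sorted(larger))
        larger.discard(victim)
        cur.excluded.add(victim)
    return cur
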