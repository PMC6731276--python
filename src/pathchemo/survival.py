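"""Survival-based validation of candidate pathway activity.

Patients are stratified into high/low activity groups by t-SNE embedding
of their pathway-activity vectors followed by 2-means clustering; the
groups are compared by Kaplan-Meier/log-rank and Cox proportional-hazards
models.  Non-randomness is assessed against two null models (random
pathway sets; random patient groups of the observed sizes) and per-patient
risk is estimated by leave-one-out logistic regression with ROC analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE

from .data_io import ClinicalTable, OmicsMatrix, PathwayCollection
from .single_sample import ActivityMatrix, sample_activity

logger = logging.getLogger(__name__)


@dataclass
class StratificationResult:
    embedding: pd.DataFrame  # sample x 2 t-SNE coordinates
    group: pd.Series  # per-sample label in {high, low}
    seed: int
    perplexity: float

    @property
    def n_per_group(self) -> dict[str, int]:
        return self.group.value_counts().to_dict()


@dataclass
class SurvivalComparison:
    hr: float
    hr_ci: tuple[float, float]
    logrank_stat: float
    logrank_p: float
    n_per_group: dict[str, int]


@dataclass
class RandomModelResult:
    observed_p: float
    null_ps: np.ndarray
    empirical_p: float
    n_draws: int


def default_perplexity(n: int) -> float:
    return float(min(10, max(2, (n - 1) // 3)))


def stratify(
    activity: ActivityMatrix,
    seed: int = 0,
    perplexity: float | None = None,
) -> StratificationResult:
    """Two-group stratification of samples by pathway activity.

    t-SNE embeds the pathway-activity vectors to 2D under a fixed seed;
    2-means (10 restarts) cuts the embedding; the cluster with the larger
    mean activity across pathways is labelled *high*.
    """
    X = activity.values.T  # samples x pathways
    if X.isna().any().any():
        X = X.dropna(axis=1, how="any")
    n = X.shape[0]
    if n < 6:
        raise ValueError("stratification needs >=6 samples")
    if perplexity is None:
        perplexity = default_perplexity(n)
    if perplexity >= (n - 1) / 3:
        raise ValueError(
            f"perplexity {perplexity} too large for n={n}; "
            f"try {default_perplexity(n)}"
        )
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        learning_rate="auto",
    ).fit_transform(X.to_numpy())
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(emb)
    labels = pd.Series(km.labels_, index=X.index)
    mean_act = X.mean(axis=1)
    cluster_means = mean_act.groupby(labels).mean()
    high_cluster = cluster_means.idxmax()
    group = labels.map(lambda c: "high" if c == high_cluster else "low")
    return StratificationResult(
        pd.DataFrame(emb, index=X.index, columns=["tsne1", "tsne2"]),
        group.rename("group"),
        seed,
        float(perplexity),
    )


def _aligned_survival(
    group: pd.Series, clinical: ClinicalTable
) -> pd.DataFrame:
    df = clinical.table.loc[list(group.index)]
    return pd.DataFrame(
        {
            "time": df["time_to_event"].astype(float),
            "event": df["event"].astype(int),
            "group": group,
        }
    )


def km_logrank(group: pd.Series, clinical: ClinicalTable) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value."""
    df = _aligned_survival(group, clinical)
    counts = df["group"].value_counts()
    if len(counts) != 2 or (counts == 0).any():
        raise ValueError("log-rank needs two non-empty groups")
    if df["event"].sum() == 0:
        logger.warning("no events in either group; log-rank degenerate")
        return 0.0, 1.0
    a = df[df["group"] == counts.index[0]]
    b = df[df["group"] == counts.index[1]]
    res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_model(
    design: pd.DataFrame,
    clinical: ClinicalTable,
    group_col: str = "group",
) -> dict:
    """Cox proportional-hazards fit with a likelihood-ratio test.

    ``design`` holds per-sample covariates (indexed by sample id); a
    categorical high/low ``group`` column is encoded as high=1.  Returns
    per-covariate HR/CI/p, the model LR test, and the headline HR from a
    univariable group-only fit when a group column is present.
    """
    df = design.copy()
    if group_col in df.columns and df[group_col].dtype == object:
        df[group_col] = (df[group_col] == "high").astype(int)
    for col in df.columns:
        if df[col].nunique() <= 1:
            raise ValueError(f"covariate {col!r} is constant")
    clin = clinical.table.loc[list(df.index)]
    df["time"] = clin["time_to_event"].astype(float).clip(lower=1e-8)
    df["event"] = clin["event"].astype(int)
    if df["event"].sum() < 1:
        raise ValueError("no events; Cox model undefined")

    cph = CoxPHFitter(penalizer=0.0)
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(
            f"Cox model failed to converge (possible complete separation): {err}"
        ) from err
    summary = cph.summary
    covariates = {
        cov: {
            "hr": float(np.exp(summary.loc[cov, "coef"])),
            "ci": (
                float(np.exp(summary.loc[cov, "coef lower 95%"])),
                float(np.exp(summary.loc[cov, "coef upper 95%"])),
            ),
            "p": float(summary.loc[cov, "p"]),
        }
        for cov in summary.index
    }
    lr = cph.log_likelihood_ratio_test()
    out = {
        "covariates": covariates,
        "lr_stat": float(lr.test_statistic),
        "lr_p": float(lr.p_value),
        "log_likelihood": float(cph.log_likelihood_),
    }
    if group_col in design.columns and design.shape[1] > 1:
        uni = cox_model(design[[group_col]], clinical, group_col=group_col)
        out["group_hr"] = uni["covariates"][group_col]["hr"]
        out["group_hr_ci"] = uni["covariates"][group_col]["ci"]
    elif group_col in design.columns:
        out["group_hr"] = covariates[group_col]["hr"]
        out["group_hr_ci"] = covariates[group_col]["ci"]
    return out


def compare_survival(
    strat: StratificationResult, clinical: ClinicalTable
) -> SurvivalComparison:
    """Headline two-group comparison: log-rank + univariable Cox HR
    (high vs low)."""
    stat, p = km_logrank(strat.group, clinical)
    fit = cox_model(strat.group.to_frame("group"), clinical)
    return SurvivalComparison(
        hr=fit["group_hr"],
        hr_ci=fit["group_hr_ci"],
        logrank_stat=stat,
        logrank_p=p,
        n_per_group=strat.n_per_group,
    )


def signature_covariate(expr: OmicsMatrix, gene_list: list[str]) -> pd.Series:
    """Per-sample mean z-score over a published marker gene list, for use
    as an adjustment covariate in multivariable Cox models."""
    genes = [g.upper() for g in gene_list]
    present = [g for g in genes if g in expr.values.index]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    sub = expr.values.loc[present]
    sd = sub.std(axis=1, ddof=1).replace(0, np.nan)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0).dropna()
    return z.mean(axis=0)


def _empirical_p(observed: float, nulls: np.ndarray) -> float:
    return (int((nulls <= observed).sum()) + 1) / (len(nulls) + 1)


def random_pathway_model(
    zscored: OmicsMatrix,
    clinical: ClinicalTable,
    collection: PathwayCollection,
    observed_p: float,
    k: int = 7,
    n_draws: int = 10000,
    seed: int = 0,
    n_perm: int = 200,
    perplexity: float | None = None,
) -> RandomModelResult:
    """Null model 1: k pathways drawn at random, activity recomputed,
    patients re-stratified, log-rank p recorded; the empirical p is the
    add-one fraction of null draws at or below the observed p."""
    if len(collection) <= k:
        raise ValueError("collection must contain more than k pathways")
    rng = np.random.default_rng(seed)
    names = collection.names
    nulls = []
    attempts = 0
    while len(nulls) < n_draws:
        attempts += 1
        if attempts > 10 * n_draws:
            raise RuntimeError("too many infeasible random draws")
        draw = list(rng.choice(names, size=k, replace=False))
        sub = collection.subset(draw)
        matrix_genes = set(zscored.feature_ids)
        if not any(p.genes & matrix_genes for p in sub):
            logger.info("infeasible draw (no overlap); resampled")
            continue
        act = sample_activity(
            zscored, sub, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        strat = stratify(act, seed=int(rng.integers(2**31)), perplexity=perplexity)
        _, p = km_logrank(strat.group, clinical)
        nulls.append(p)
    nulls = np.asarray(nulls)
    return RandomModelResult(observed_p, nulls, _empirical_p(observed_p, nulls),
                             n_draws)


def random_group_model(
    group: pd.Series,
    clinical: ClinicalTable,
    observed_p: float,
    n_draws: int = 10000,
    seed: int = 0,
) -> RandomModelResult:
    """Null model 2: random patient partitions with the observed group
    sizes, compared by log-rank."""
    rng = np.random.default_rng(seed)
    samples = np.asarray(group.index)
    n_high = int((group == "high").sum())
    nulls = np.empty(n_draws)
    for i in range(n_draws):
        perm = rng.permutation(samples)
        g = pd.Series("low", index=samples)
        g.loc[perm[:n_high]] = "high"
        _, nulls[i] = km_logrank(g, clinical)
    return RandomModelResult(observed_p, nulls, _empirical_p(observed_p, nulls),
                             n_draws)


def loocv_risk(
    activity: ActivityMatrix,
    outcome: pd.Series,
    C: float = 1e6,
) -> tuple[pd.Series, float]:
    """Leave-one-out logistic regression of a binary outcome on pathway
    activities: per-sample held-out risk and accuracy at the 0.5 cut.

    A near-unpenalized fit is tried first; if the fold separates perfectly
    (saturated probabilities), a ridge-penalized fallback is used and
    flagged.
    """
    X = activity.values.T.dropna(axis=1, how="any")
    y = outcome.loc[X.index].astype(int)
    if len(X) < 8:
        raise ValueError("LOOCV requires n >= 8")
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    risks = pd.Series(index=X.index, dtype=float)
    for held in X.index:
        train = X.index != held
        ytr = y[train]
        if ytr.nunique() < 2:
            risks.loc[held] = float(ytr.iloc[0])
            continue
        model = LogisticRegression(C=C, max_iter=5000)
        model.fit(X[train], ytr)
        prob = model.predict_proba(X.loc[[held]])[0, 1]
        if not np.isfinite(prob):
            logger.warning("separation in fold %s; ridge fallback", held)
            model = LogisticRegression(C=1.0, max_iter=5000)
            model.fit(X[train], ytr)
            prob = model.predict_proba(X.loc[[held]])[0, 1]
        risks.loc[held] = float(prob)
    accuracy = float(((risks >= 0.5).astype(int) == y).mean())
    return risks, accuracy


def roc_auc(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> float:
    """Area under the ROC curve via the concordant-pair (Mann-Whitney)
    formulation; tied scores count one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg)))
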