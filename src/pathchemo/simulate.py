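"""Synthetic multi-omics cohorts with planted dual-level pathway signal.

The generator emulates the statistical structure the discovery pipeline
assumes: two response groups; a pathway collection of disjoint gene sets;
Gaussian expression noise with a configurable mean shift planted in the
poor-response group for selected pathways; beta-distributed methylation
(per-site Beta base level, per-sample Beta noise at fixed concentration)
with a planted beta-shift; 1-3 CpG sites per gene; and exponential
survival whose log-hazard is proportional to each sample's mean expression
over the planted pathways, censored uniformly to a configured fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    ClinicalTable,
    OmicsMatrix,
    Pathway,
    PathwayCollection,
    SiteGeneMap,
)
from .signatures import ResponseGroups
from .single_sample import ActivityMatrix

PLANTED_LEVELS = ("expression", "methylation", "both")


@dataclass
class SyntheticConfig:
    n_pathways: int = 100
    genes_per_pathway: int = 30
    n_poor: int = 4
    n_favorable: int = 4
    n_planted: int = 5
    planted_level: str = "both"  # level applied to every planted pathway
    expr_effect: float = 2.0  # mean shift in the poor group, sigma units
    meth_effect: float = 0.2  # beta shift in the poor group
    noise_sigma: float = 1.0
    beta_base: tuple[float, float] = (2.0, 5.0)  # Beta(a, b) for site means
    beta_concentration: float = 50.0  # per-sample Beta noise around site mean
    baseline_hazard: float = np.log(2) / 365.0  # per day
    activity_coef: float = 1.0  # log-hazard per unit planted-activity
    censoring: float = 0.3
    max_sites_per_gene: int = 3
    therapy: str = "carboplatin-paclitaxel"

    def __post_init__(self) -> None:
        if self.planted_level not in PLANTED_LEVELS:
            raise ValueError(f"planted_level must be one of {PLANTED_LEVELS}")
        if self.n_planted > self.n_pathways:
            raise ValueError("more planted pathways than pathways")
        if not 0 <= self.meth_effect <= 1:
            raise ValueError("meth_effect must keep beta shiftable within [0, 1]")
        if not 0 <= self.censoring < 1:
            raise ValueError("censoring fraction must be in [0, 1)")
        for name, v in (
            ("n_pathways", self.n_pathways),
            ("genes_per_pathway", self.genes_per_pathway),
            ("n_poor", self.n_poor),
            ("n_favorable", self.n_favorable),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_genes(self) -> int:
        return self.n_pathways * self.genes_per_pathway

    @property
    def n_samples(self) -> int:
        return self.n_poor + self.n_favorable


@dataclass
class SyntheticCohort:
    expression: OmicsMatrix
    methylation: OmicsMatrix
    site_gene_map: SiteGeneMap
    clinical: ClinicalTable
    collection: PathwayCollection
    groups: ResponseGroups
    truth: list[tuple[str, str]]  # (pathway, level)
    planted_activity: pd.Series  # per-sample mean planted expression


def _pathway_name(i: int) -> str:
    return f"PW{i + 1:03d}"


def _gene_name(i: int) -> str:
    return f"G{i + 1:05d}"


def planted_truth(config: SyntheticConfig) -> list[tuple[str, str]]:
    """The exact planted pathway/level list :func:`generate` uses; a pure
    function of the config (the first ``n_planted`` pathways), stable under
    any seed."""
    return [
        (_pathway_name(i), config.planted_level) for i in range(config.n_planted)
    ]


def generate(config: SyntheticConfig, seed: int = 0) -> SyntheticCohort:
    """Draw a full synthetic cohort; bit-reproducible under (config, seed)."""
    rng = np.random.default_rng(seed)
    genes = [_gene_name(i) for i in range(config.n_genes)]
    pathways = [
        Pathway(
            _pathway_name(i),
            "synthetic",
            frozenset(
                genes[i * config.genes_per_pathway : (i + 1) * config.genes_per_pathway]
            ),
        )
        for i in range(config.n_pathways)
    ]
    collection = PathwayCollection(pathways)
    truth = planted_truth(config)
    planted_expr_genes: set[str] = set()
    planted_meth_genes: set[str] = set()
    for name, level in truth:
        pw_genes = collection[name].genes
        if level in ("expression", "both"):
            planted_expr_genes |= pw_genes
        if level in ("methylation", "both"):
            planted_meth_genes |= pw_genes

    poor_ids = [f"S{i + 1:03d}" for i in range(config.n_poor)]
    fav_ids = [f"S{i + 1:03d}" for i in range(config.n_poor, config.n_samples)]
    samples = poor_ids + fav_ids

    # expression: Gaussian noise, planted genes shifted in the poor group
    expr = rng.normal(0.0, config.noise_sigma, (config.n_genes, config.n_samples))
    shift = config.expr_effect * config.noise_sigma
    planted_rows = np.fromiter((g in planted_expr_genes for g in genes), bool)
    expr[np.ix_(planted_rows, np.arange(config.n_poor))] += shift
    expression = OmicsMatrix(
        pd.DataFrame(expr, index=genes, columns=samples), "expression"
    )

    # methylation: 1-3 sites per gene, Beta site means, Beta per-sample noise
    n_sites_per_gene = rng.integers(1, config.max_sites_per_gene + 1, config.n_genes)
    site_ids, site_genes = [], []
    for g, n_s in zip(genes, n_sites_per_gene):
        for j in range(n_s):
            site_ids.append(f"cg_{g}_{j + 1}")
            site_genes.append(g)
    n_sites = len(site_ids)
    a, b = config.beta_base
    site_means = rng.beta(a, b, n_sites)
    means = np.tile(site_means[:, None], (1, config.n_samples))
    planted_site = np.fromiter((g in planted_meth_genes for g in site_genes), bool)
    means[np.ix_(planted_site, np.arange(config.n_poor))] += config.meth_effect
    means = np.clip(means, 0.02, 0.98)
    kappa = config.beta_concentration
    beta_vals = rng.beta(means * kappa, (1 - means) * kappa)
    methylation = OmicsMatrix(
        pd.DataFrame(beta_vals, index=site_ids, columns=samples), "beta"
    )
    sg_map = SiteGeneMap(pd.DataFrame({"site_id": site_ids, "gene": site_genes}))

    # survival: exponential, log-hazard proportional to planted activity
    if planted_expr_genes:
        activity = expression.values.loc[sorted(planted_expr_genes)].mean(axis=0)
    else:
        activity = pd.Series(0.0, index=samples)
    hazard = config.baseline_hazard * np.exp(
        config.activity_coef * activity.to_numpy()
    )
    t_true = rng.exponential(1.0 / hazard)
    event = np.ones(config.n_samples, dtype=int)
    time = t_true.copy()
    n_cens = int(round(config.censoring * config.n_samples))
    if n_cens:
        cens_idx = rng.choice(config.n_samples, size=n_cens, replace=False)
        time[cens_idx] = rng.uniform(0.0, t_true[cens_idx])
        event[cens_idx] = 0
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "therapy": config.therapy,
                "time_to_event": np.round(time, 2),
                "event": event,
                "age": np.round(rng.normal(65, 8, config.n_samples), 1),
                "gender": rng.choice(["male", "female"], config.n_samples),
                "stage": rng.choice(["I", "II", "III"], config.n_samples),
                "neoadjuvant": 0,
            }
        )
    )
    groups = ResponseGroups(set(poor_ids), set(fav_ids), set(), (365.0, 730.0))
    return SyntheticCohort(
        expression, methylation, sg_map, clinical, collection, groups, truth,
        activity,
    )


def generate_activity_cohort(
    n_high: int = 20,
    n_low: int = 20,
    n_pathways: int = 7,
    delta: float = 5.0,
    sigma: float = 0.5,
    hazard_ratio: float = 4.0,
    baseline_hazard: float = np.log(2) / 365.0,
    censoring: float = 0.3,
    seed: int = 0,
) -> tuple[ActivityMatrix, ClinicalTable, pd.Series]:
    """A validation-style cohort sampled directly in activity space.

    High-activity patients have pathway activities shifted by ``delta``
    (Gaussian noise ``sigma``) and their hazard multiplied by
    ``hazard_ratio`` on an exponential baseline; censoring picks a uniform
    time before the true event for a random ``censoring`` fraction.
    Returns the activity matrix, clinical table and true group labels.
    """
    rng = np.random.default_rng(seed)
    n = n_high + n_low
    samples = [f"V{i + 1:03d}" for i in range(n)]
    truth = pd.Series(["high"] * n_high + ["low"] * n_low, index=samples)
    act = rng.normal(0.0, sigma, (n_pathways, n))
    act[:, :n_high] += delta
    names = [_pathway_name(i) for i in range(n_pathways)]
    values = pd.DataFrame(act, index=names, columns=samples)
    activity = ActivityMatrix(
        values, pd.DataFrame("signed", index=names, columns=samples), "expression"
    )
    hazard = np.where(truth == "high", baseline_hazard * hazard_ratio,
                      baseline_hazard)
    t_true = rng.exponential(1.0 / hazard)
    event = np.ones(n, dtype=int)
    time = t_true.copy()
    n_cens = int(round(censoring * n))
    if n_cens:
        idx = rng.choice(n, size=n_cens, replace=False)
        time[idx] = rng.uniform(0.0, t_true[idx])
        event[idx] = 0
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "therapy": "carboplatin-paclitaxel",
                "time_to_event": np.round(time, 2),
                "event": event,
                "age": np.round(rng.normal(65, 8, n), 1),
                "gender": rng.choice(["male", "female"], n),
                "stage": rng.choice(["I", "II", "III"], n),
                "neoadjuvant": 0,
            }
        )
    )
    return activity, clinical, truth
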