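"""Containers and readers/writers for the omics, clinical and pathway inputs.

The pipeline works on three tabular inputs — a gene x sample expression
matrix, a CpG-site x sample methylation matrix of beta values with a
site-to-gene map, and a clinical/treatment table — plus a pathway collection
in GMT format.  All tabular files are tab-separated text; gene symbols are
uppercased on load so joins between matrices and gene sets are deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Space = Literal["expression", "beta", "mvalue"]

VALID_REGIONS = {"TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR"}

CLINICAL_COLUMNS = [
    "sample_id",
    "therapy",
    "time_to_event",
    "event",
    "age",
    "gender",
    "stage",
    "neoadjuvant",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class OmicsMatrix:
    """A feature x sample matrix of expression, beta or M values.

    ``values`` is a pandas DataFrame indexed by feature id (gene symbol or
    CpG id) with sample ids as columns.  ``space`` declares the value space;
    beta matrices are validated to [0, 1].
    """

    values: pd.DataFrame
    space: Space

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.space == "beta":
            vals = self.values.to_numpy(dtype=float)
            bad = (vals < 0) | (vals > 1)
            if bad.any():
                rows, cols_ = np.nonzero(bad)
                cells = [
                    f"({idx[r]}, {self.values.columns[c]})={vals[r, c]}"
                    for r, c in zip(rows[:10], cols_[:10])
                ]
                raise ValueError(
                    f"beta values outside [0, 1] in {bad.sum()} cells: "
                    + "; ".join(cells)
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return OmicsMatrix(self.values.loc[:, list(sample_ids)], self.space)


@dataclass
class SiteGeneMap:
    """CpG site to gene assignment, optionally with a genomic-region label.

    A site may map to more than one gene (one row per site-gene pair); each
    mapped gene receives the site independently.
    """

    table: pd.DataFrame  # columns: site_id, gene, region (region may be NA)

    def __post_init__(self) -> None:
        required = {"site_id", "gene"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"map requires columns {sorted(required)}")
        if "region" not in self.table.columns:
            self.table = self.table.assign(region=pd.NA)
        bad = self.table["region"].dropna().loc[
            lambda s: ~s.isin(VALID_REGIONS)
        ]
        if len(bad):
            raise ValueError(f"unknown region labels: {sorted(bad.unique())}")
        self.table = self.table.assign(gene=self.table["gene"].str.upper())

    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    def sites_for_gene(self, gene: str) -> list[str]:
        sub = self.table.loc[self.table["gene"] == gene.upper(), "site_id"]
        return sorted(sub.unique())


@dataclass
class ClinicalTable:
    """One row per sample: therapy, time-to-event (days), event indicator,
    age, gender, stage and a neoadjuvant flag."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        if (self.table["time_to_event"] < 0).any():
            raise ValueError("negative time_to_event")
        if not self.table["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        self.table = self.table.set_index(
            self.table["sample_id"].astype(str), drop=False
        )
        self.table.index.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(sample_ids)].reset_index(drop=True))


@dataclass(frozen=True)
class Pathway:
    name: str
    description: str
    genes: frozenset[str]


@dataclass
class PathwayCollection:
    """An ordered collection of named gene sets (GMT semantics)."""

    pathways: list[Pathway] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.pathways]
        if len(names) != len(set(names)):
            seen: set[str] = set()
            dups = sorted({n for n in names if n in seen or seen.add(n)})
            raise ValueError(f"duplicate pathway names: {dups}")
        for p in self.pathways:
            if not p.genes:
                raise ValueError(f"pathway {p.name!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, name: str) -> Pathway:
        for p in self.pathways:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pathways]

    def subset(self, names: Iterable[str]) -> "PathwayCollection":
        wanted = list(names)
        return PathwayCollection([self[n] for n in wanted])


# ---------------------------------------------------------------------------
# readers / writers


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT file: one pathway per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a set are deduplicated; gene symbols are
    uppercased.  A line with fewer than three fields is a parse error
    naming the line number.
    """
    path = Path(path)
    pathways: list[Pathway] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            genes = []
            seen = set()
            for g in fields[2:]:
                g = g.strip().upper()
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            pathways.append(Pathway(name, desc, frozenset(genes)))
    if not pathways:
        logger.warning("GMT file %s contains no pathways", path)
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in collection:
            fh.write("\t".join([p.name, p.description, *sorted(p.genes)]) + "\n")


def read_matrix(path: str | Path, space: Space) -> OmicsMatrix:
    """Read a feature x sample TSV matrix (first row sample ids, first
    column feature ids) into the declared value space."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if space == "expression":
        df.index = df.index.str.upper()
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate feature ids {dups}")
    return OmicsMatrix(df.astype(float), space)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.table.to_csv(path, sep="\t", index=False)


def read_site_gene_map(path: str | Path) -> SiteGeneMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SiteGeneMap(df)


def write_site_gene_map(sg_map: SiteGeneMap, path: str | Path) -> None:
    sg_map.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# value-space conversions


def beta_to_m(beta, epsilon: float = 1e-6):
    """Logit-2 transform of methylation fraction: M = log2(beta / (1 - beta)).

    Beta is clipped to [epsilon, 1 - epsilon] first so boundary values map to
    finite M while preserving ordering.  Accepts scalars or arrays.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    arr = np.asarray(beta, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("beta values must be in [0, 1]")
    clipped = np.clip(arr, epsilon, 1 - epsilon)
    out = np.log2(clipped / (1 - clipped))
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    arr = np.asarray(m, dtype=float)
    out = np.exp2(arr) / (1 + np.exp2(arr))
    return out if out.ndim else float(out)


def matrix_beta_to_m(matrix: OmicsMatrix, epsilon: float = 1e-6) -> OmicsMatrix:
    if matrix.space != "beta":
        raise ValueError("input matrix must be in beta space")
    vals = beta_to_m(matrix.values.to_numpy(), epsilon=epsilon)
    return OmicsMatrix(
        pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns),
        "mvalue",
    )


def select_site_per_gene(
    meth: OmicsMatrix, sg_map: SiteGeneMap
) -> tuple[OmicsMatrix, pd.Series]:
    """Collapse a site-level beta matrix to one CpG site per gene.

    For every gene the mapped site with the highest coefficient of variation
    (sd / mean of beta across all samples) is kept; ties break to the
    lexicographically smallest site id.  Genes whose sites are all absent
    from the matrix are dropped with a warning.  Returns the gene-keyed
    matrix and a gene -> chosen-site Series.
    """
    if meth.space != "beta":
        raise ValueError("site selection operates on beta values")
    vals = meth.values
    means = vals.mean(axis=1)
    sds = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (sds / means).replace([np.inf, -np.inf], np.nan).fillna(0.0)

    chosen: dict[str, str] = {}
    dropped: list[str] = []
    for gene, sub in sg_map.table.groupby("gene"):
        sites = [s for s in sub["site_id"].unique() if s in vals.index]
        if not sites:
            dropped.append(gene)
            continue
        sites = sorted(sites)  # lexicographic tie-break via stable idxmax
        site_cv = cv.loc[sites]
        chosen[gene] = site_cv.index[int(np.argmax(site_cv.to_numpy()))]
    if dropped:
        logger.warning(
            "%d genes dropped (no mapped sites in matrix): %s",
            len(dropped),
            dropped[:10],
        )
    if not chosen:
        raise ValueError("no gene has a mapped site present in the matrix")
    genes = sorted(chosen)
    out = vals.loc[[chosen[g] for g in genes]].copy()
    out.index = genes
    return OmicsMatrix(out, "beta"), pd.Series({g: chosen[g] for g in genes})
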