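"""Normalization, cell-class harmonization and pseudobulk aggregation.

Counts are always aggregated first (summing raw counts over the cells of
a group) and the aggregate is then normalized as if it were a single
cell, so both normalization modes share one convention.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from devclock.simulate import BROAD_CLASSES, MultiStudyDataset

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("lognorm", "ranknorm", "raw")


@dataclass
class PseudobulkMatrix:
    """Gene x group expression with one metadata row per column.

    ``groups`` columns: study_id, sample_id, age_pcw, n_cells and, when
    grouped by class, broad_class.  ``normalization`` records how the
    aggregated counts were transformed and is enforced at predict time.
    """

    values: np.ndarray  # genes x groups
    genes: list[str]
    groups: pd.DataFrame
    normalization: str = "lognorm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.groups)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.groups)} groups"
            )
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if "n_cells" in self.groups and (self.groups["n_cells"] <= 0).any():
            raise ValueError("groups with n_cells <= 0")

    @property
    def n_groups(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "PseudobulkMatrix":
        index = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"{len(missing)} genes absent, e.g. {missing[:3]}")
        idx = [index[g] for g in genes]
        return PseudobulkMatrix(
            values=self.values[idx],
            genes=list(genes),
            groups=self.groups.copy(),
            normalization=self.normalization,
        )

    def subset_groups(self, mask: np.ndarray) -> "PseudobulkMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return PseudobulkMatrix(
            values=self.values[:, idx],
            genes=list(self.genes),
            groups=self.groups.iloc[idx].reset_index(drop=True),
            normalization=self.normalization,
        )


@dataclass
class ClassMapping:
    """Author cell-type label -> broad class lookup."""

    lookup: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.lookup.values()} - set(BROAD_CLASSES)
        if bad:
            raise ValueError(f"mapping targets outside broad classes: {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "ClassMapping":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValueError("class mapping TSV needs two columns (author_label, broad_class)")
        return cls(lookup=dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))


def log_normalize(counts: sp.spmatrix | np.ndarray, scale_factor: float = 10_000.0) -> np.ndarray:
    """Library-size log normalization: ln(1 + scale_factor * c / total).

    ``counts`` is genes x cells; each column (cell) is scaled by its own
    total, so the output is invariant to per-cell depth.  Cells with zero
    total are dropped-with-warning upstream; here they raise.
    """
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts, dtype=float)
    if (dense < 0).any():
        raise ValueError("negative counts")
    totals = dense.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("cell with zero total count; filter before normalizing")
    return np.log1p(scale_factor * dense / totals)


def rank_normalize(counts: sp.spmatrix | np.ndarray) -> np.ndarray:
    """Within-cell rank normalization.

    Per cell, every gene's count is replaced by its ascending rank among
    all genes of that cell (ties averaged, zeros included) divided by the
    number of genes, giving values in (0, 1].  Invariant to any strictly
    monotone per-cell transform of counts.
    """
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts, dtype=float)
    if dense.shape[0] == 0:
        raise ValueError("zero genes")
    ranks = rankdata(dense, axis=0, method="average")
    return ranks / dense.shape[0]


def map_cell_classes(
    cells: pd.DataFrame,
    mapping: ClassMapping | dict[str, str],
    allow_unmapped: bool = False,
) -> pd.DataFrame:
    """Assign ``broad_class`` from ``author_cell_type`` via a lookup.

    Unmapped labels raise (listing the offenders) unless
    ``allow_unmapped`` is set, in which case they are assigned "Others"
    and counted in the log.
    """
    lookup = mapping.lookup if isinstance(mapping, ClassMapping) else dict(mapping)
    out = cells.copy()
    labels = out["author_cell_type"].astype(str)
    mapped = labels.map(lookup)
    unmapped = mapped.isna()
    if unmapped.any():
        offenders = sorted(labels[unmapped].unique())
        if not allow_unmapped:
            raise KeyError(f"unmapped author cell types: {offenders}")
        logger.warning(
            "%d cells with %d unmapped labels assigned to Others: %s",
            int(unmapped.sum()), len(offenders), offenders,
        )
        mapped = mapped.fillna("Others")
    out["broad_class"] = mapped.to_numpy()
    return out


def pseudobulk(
    dataset: MultiStudyDataset,
    group_keys: str = "sample_class",
    min_cells: int = 1,
    normalization: str = "lognorm",
    scale_factor: float = 10_000.0,
) -> PseudobulkMatrix:
    """Aggregate cells into pseudobulk profiles.

    ``group_keys`` is ``"sample"`` (one group per sample) or
    ``"sample_class"`` (one group per sample x broad class).  Raw counts
    are summed per group, then the aggregate column is normalized per the
    requested mode as if it were one cell.  Groups with fewer than
    ``min_cells`` cells are dropped and logged.
    """
    if group_keys not in ("sample", "sample_class"):
        raise ValueError("group_keys must be 'sample' or 'sample_class'")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    cells = dataset.cells
    keys = ["study_id", "sample_id"]
    if group_keys == "sample_class":
        if "broad_class" not in cells:
            raise ValueError("broad_class required for sample_class grouping")
        keys = keys + ["broad_class"]

    codes, uniques = pd.factorize(pd.MultiIndex.from_frame(cells[keys]))
    if len(uniques) == 0:
        raise ValueError("empty grouping")
    n_groups = len(uniques)
    # group-sum via sparse indicator
    indicator = sp.csr_matrix(
        (np.ones(len(codes)), (np.arange(len(codes)), codes)),
        shape=(len(codes), n_groups),
    )
    sums = np.asarray((dataset.counts @ indicator).todense(), dtype=float)
    n_cells = np.bincount(codes, minlength=n_groups)

    meta = pd.DataFrame(list(uniques), columns=keys)
    ages = cells.groupby(keys, sort=False)["age_pcw"].first()
    meta["age_pcw"] = ages.loc[pd.MultiIndex.from_frame(meta[keys])].to_numpy()
    meta["n_cells"] = n_cells

    keep = n_cells >= min_cells
    totals = sums.sum(axis=0)
    zero_total = totals == 0
    if zero_total.any():
        logger.warning("dropping %d pseudobulk groups with zero total counts", int(zero_total.sum()))
        keep &= ~zero_total
    if (~keep).any():
        logger.info("dropping %d groups under min_cells=%d", int((~keep).sum()), min_cells)
    sums = sums[:, keep]
    meta = meta.loc[keep].reset_index(drop=True)
    if sums.shape[1] == 0:
        raise ValueError("no groups left after filtering")

    if normalization == "lognorm":
        values = log_normalize(sums, scale_factor=scale_factor)
    elif normalization == "ranknorm":
        values = rank_normalize(sums)
    elif normalization == "raw":
        values = sums
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return PseudobulkMatrix(values=values, genes=list(dataset.genes), groups=meta, normalization=normalization)


def intersect_genes(datasets: Sequence[MultiStudyDataset]) -> list[str]:
    """Sorted intersection of gene identifiers across datasets."""
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    common = set(datasets[0].genes)
    for ds in datasets[1:]:
        common &= set(ds.genes)
    if not common:
        raise ValueError("empty gene intersection")
    return sorted(common)


def align_to_genes(dataset: MultiStudyDataset, genes: Sequence[str]) -> MultiStudyDataset:
    """Row-subset and re-order a dataset to a gene list."""
    index = {g: i for i, g in enumerate(dataset.genes)}
    missing = [g for g in genes if g not in index]
    if missing:
        raise KeyError(f"{len(missing)} genes absent from dataset, e.g. {missing[:3]}")
    idx = [index[g] for g in genes]
    return MultiStudyDataset(
        counts=dataset.counts[idx].tocsr(),
        genes=list(genes),
        cells=dataset.cells.copy(),
        species=dataset.species,
    )
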