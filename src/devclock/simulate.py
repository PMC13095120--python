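"""Synthetic multi-study single-cell data with known generative truth.

The generator emulates the statistical structure of a multi-laboratory
collection of developing-brain scRNA-seq datasets:

* tissue composition drifts with age following per-class logistic curves
  (progenitors fall, astrocytes and oligodendrocytes rise);
* a set of "informative" genes carries a cell-autonomous, monotone age
  program (positive or negative log-linear slope per post-conception week);
* informative genes belong to co-expression modules driven by shared
  per-sample latent factors;
* each study adds a per-gene multiplicative batch effect, each cell has
  its own library size, and counts are multinomial given per-cell rates;
* a species "tempo factor" rescales the speed of the transcriptional
  clock, so a fast species traverses the same programs in fewer weeks.

Every generative parameter is returned as a :class:`SyntheticTruth` so
downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.special import expit

BROAD_CLASSES: tuple[str, ...] = (
    "Astrocyte",
    "Progenitor",
    "Neuron",
    "Oligodendrocyte",
    "Immune",
    "Vascular",
    "Others",
)

CELLS_TSV_COLUMNS = (
    "cell_id",
    "study_id",
    "sample_id",
    "age_pcw",
    "author_cell_type",
    "broad_class",
    "species",
)


@dataclass(frozen=True)
class CompositionCurve:
    """Logistic cell-class proportion curve over age.

    proportion(age) = floor + (ceiling - floor) * sigmoid(steepness * (age - midpoint))

    A negative ``steepness`` gives a falling curve.  ``floor``/``ceiling``
    are the asymptotic proportions (both in [0, 1]).
    """

    midpoint: float
    steepness: float
    floor: float
    ceiling: float

    def __call__(self, age: np.ndarray | float) -> np.ndarray | float:
        return self.floor + (self.ceiling - self.floor) * expit(
            self.steepness * (np.asarray(age, dtype=float) - self.midpoint)
        )


def default_composition() -> dict[str, CompositionCurve]:
    """Default class-proportion curves over 6-30 pcw.

    Progenitors fall from ~0.55 to ~0.08; astrocytes rise from ~0 to
    ~0.25 and oligodendrocytes from ~0 to ~0.10 in the third trimester;
    immune/vascular/other fractions stay small and flat.  The balance
    class (Neuron by default) absorbs the remainder, rising through
    neurogenesis as progenitors are consumed.
    """
    return {
        "Progenitor": CompositionCurve(midpoint=16.0, steepness=-0.35, floor=0.08, ceiling=0.55),
        "Astrocyte": CompositionCurve(midpoint=20.0, steepness=0.35, floor=0.0, ceiling=0.25),
        "Oligodendrocyte": CompositionCurve(midpoint=26.0, steepness=0.4, floor=0.0, ceiling=0.10),
        "Immune": CompositionCurve(midpoint=18.0, steepness=0.0, floor=0.04, ceiling=0.04),
        "Vascular": CompositionCurve(midpoint=18.0, steepness=0.0, floor=0.03, ceiling=0.03),
        "Others": CompositionCurve(midpoint=18.0, steepness=0.0, floor=0.05, ceiling=0.05),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the multi-study generator.

    Ages are post-conception weeks (pcw) throughout; ages on other clocks
    (embryonic days, days in vitro) must be divided by 7 at the interface.

    ``composition_params`` gives a logistic curve for every broad class
    except ``balance_class``, whose proportion is defined as one minus the
    rest — this guarantees proportions sum to exactly 1 at every age; a
    configuration whose balance goes negative is rejected.

    ``signal_class`` restricts the cell-autonomous age program to a single
    class (class-private signal); ``None`` means the program is shared by
    all classes (cell type-agnostic signal, the default).

    ``module_study_activity`` is the probability that a module's age
    program is active in a given study; values below 1 make modules
    study-specific (each module's genes are age-correlated only in the
    studies where it is active), which is what separates modules in the
    aggregate co-expression network.  ``module_sd`` adds a per-(sample,
    module) latent factor shared by member genes on top of the program.

    Compositional noise has two levels: ``composition_noise_sd`` is
    per-sample (donor/dissection) log-scale jitter of class weights and
    ``composition_study_sd`` is a per-study (annotation/protocol) offset;
    classes listed in ``composition_stable_classes`` are exempt from
    both, emulating well-defined cell classes whose proportions are
    annotated consistently across laboratories.  Jittered weights are
    renormalized, so realized proportions still sum to 1.
    """

    n_studies: int = 6
    samples_per_study: int = 8
    ages: tuple[float, ...] = tuple(float(a) for a in np.linspace(6.0, 30.0, 8))
    cells_per_sample: int = 300
    n_genes: int = 2000
    n_positive_genes: int = 100
    n_negative_genes: int = 100
    n_modules: int = 6
    composition_params: dict[str, CompositionCurve] = field(default_factory=default_composition)
    balance_class: str = "Neuron"
    composition_noise_sd: float = 0.0
    composition_study_sd: float = 0.0
    composition_stable_classes: tuple[str, ...] = ()
    batch_sd: float = 0.15
    depth_range: tuple[int, int] = (1000, 5000)
    noise_sd: float = 0.1
    tempo_factor: float = 1.0
    age_center: float = 18.0
    slope_range: tuple[float, float] = (0.03, 0.08)
    module_sd: float = 0.3
    module_study_activity: float = 1.0
    class_profile_sd: float = 0.5
    signal_class: str | None = None
    species: str = "human"
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies < 1 or self.samples_per_study < 1:
            raise ValueError("n_studies and samples_per_study must be positive")
        if len(self.ages) == 0:
            raise ValueError("ages must be non-empty")
        if len(self.ages) != self.samples_per_study:
            raise ValueError(
                f"ages has {len(self.ages)} entries but samples_per_study={self.samples_per_study}"
            )
        if self.cells_per_sample < 1 or self.n_genes < 1:
            raise ValueError("cells_per_sample and n_genes must be positive")
        if self.n_positive_genes + self.n_negative_genes > self.n_genes:
            raise ValueError("more informative genes than genes")
        if self.tempo_factor <= 0:
            raise ValueError("tempo_factor must be > 0")
        if not (0 < self.module_study_activity <= 1):
            raise ValueError("module_study_activity must be in (0, 1]")
        if not (0 < self.depth_range[0] <= self.depth_range[1]):
            raise ValueError("depth_range must be positive and ordered")
        if self.balance_class in self.composition_params:
            raise ValueError("balance_class must not appear in composition_params")
        unknown = set(self.composition_params) - set(BROAD_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in composition_params: {sorted(unknown)}")
        if self.balance_class not in BROAD_CLASSES:
            raise ValueError(f"unknown balance_class {self.balance_class!r}")
        for age in self.ages:
            props = self.class_proportions(age)
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"class proportions sum to {total} at age {age}")
            if any(p < -1e-12 for p in props.values()):
                raise ValueError(f"negative class proportion at age {age} (balance underflow)")

    def class_proportions(self, age: float) -> dict[str, float]:
        """Class proportion of each broad class at ``age`` (sums to 1)."""
        props = {c: float(curve(age)) for c, curve in self.composition_params.items()}
        props[self.balance_class] = 1.0 - sum(props.values())
        return {c: props.get(c, 0.0) for c in BROAD_CLASSES}


@dataclass
class SyntheticTruth:
    """Generative parameters recorded for recovery tests."""

    gene_slopes: np.ndarray  # expected log-expression change per pcw
    gene_module: np.ndarray  # module id per gene, -1 for none
    class_proportion_curves: Callable[[float], dict[str, float]]
    tempo_factor: float
    study_batch_effects: pd.DataFrame  # studies x genes, log-scale
    module_study_activity: pd.DataFrame  # studies x modules, 0/1
    baselines: np.ndarray
    class_profiles: pd.DataFrame  # classes x genes, log-scale offsets
    config: SimulationConfig


@dataclass
class MultiStudyDataset:
    """Sparse gene x cell counts plus per-cell metadata.

    ``counts`` is genes x cells (CSR, non-negative integers); ``cells``
    has one row per column of ``counts`` with columns
    cell_id, study_id, sample_id, age_pcw, author_cell_type, broad_class.
    """

    counts: sp.csr_matrix
    genes: list[str]
    cells: pd.DataFrame
    species: str = "human"

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        missing = [c for c in ("cell_id", "study_id", "sample_id", "age_pcw") if c not in self.cells]
        if missing:
            raise ValueError(f"cells table missing columns: {missing}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def equals(self, other: "MultiStudyDataset") -> bool:
        if self.genes != other.genes or self.species != other.species:
            return False
        if (self.counts != other.counts).nnz != 0:
            return False
        a = self.cells.reset_index(drop=True)
        b = other.cells.reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a[list(CELLS_TSV_COLUMNS[:-1])], b[list(CELLS_TSV_COLUMNS[:-1])])
        except AssertionError:
            return False
        return True

    def subset_cells(self, mask: np.ndarray) -> "MultiStudyDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return MultiStudyDataset(
            counts=self.counts[:, idx].tocsr(),
            genes=list(self.genes),
            cells=self.cells.iloc[idx].reset_index(drop=True),
            species=self.species,
        )

    def to_anndata(self):
        """Cells x genes AnnData view (copies data)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cells.set_index("cell_id"),
            var=pd.DataFrame(index=pd.Index(self.genes, name="gene")),
        )


@dataclass
class OrthologMap:
    """Gene correspondence between two species.

    ``records`` columns: gene_a, gene_b, orthogroup.  In ``one_to_one``
    mode each gene appears at most once per species.
    """

    records: pd.DataFrame
    mode: str = "one_to_one"

    def __post_init__(self) -> None:
        if self.mode not in ("one_to_one", "orthogroup"):
            raise ValueError(f"unknown mode {self.mode!r}")
        need = {"gene_a", "gene_b", "orthogroup"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(need)}")
        if self.mode == "one_to_one":
            if self.records["gene_a"].duplicated().any() or self.records["gene_b"].duplicated().any():
                raise ValueError("one_to_one map has duplicated genes")

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, mode: str = "one_to_one") -> "OrthologMap":
        return cls(records=pd.read_csv(path, sep="\t"), mode=mode)


@dataclass
class _GeneParams:
    """Gene-level generative parameters shared across species."""

    baselines: np.ndarray
    slopes: np.ndarray
    modules: np.ndarray
    class_profiles: np.ndarray  # n_classes x n_genes


def _draw_gene_params(config: SimulationConfig, rng: np.random.Generator) -> _GeneParams:
    n = config.n_genes
    baselines = rng.normal(0.0, 1.0, size=n)
    slopes = np.zeros(n)
    lo, hi = config.slope_range
    npos, nneg = config.n_positive_genes, config.n_negative_genes
    slopes[:npos] = rng.uniform(lo, hi, size=npos)
    slopes[npos : npos + nneg] = -rng.uniform(lo, hi, size=nneg)
    modules = np.full(n, -1, dtype=int)
    if config.n_modules > 0:
        # modules mix positive- and negative-program genes: the latent
        # factor is a shared state signal orthogonal to the sign of the
        # age program
        informative = np.arange(npos + nneg)
        modules[informative] = informative % config.n_modules
    class_profiles = rng.normal(0.0, config.class_profile_sd, size=(len(BROAD_CLASSES), n))
    return _GeneParams(baselines, slopes, modules, class_profiles)


def _gene_names(n: int, prefix: str = "gene") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _simulate_counts(
    config: SimulationConfig,
    params: _GeneParams,
    rng: np.random.Generator,
    study_prefix: str = "study",
) -> tuple[MultiStudyDataset, pd.DataFrame, pd.DataFrame]:
    """Draw cells for every study/sample given fixed gene parameters.

    Returns the dataset, the per-study batch-effect table and the
    module-by-study activity table.
    """
    n_genes = config.n_genes
    class_index = {c: i for i, c in enumerate(BROAD_CLASSES)}
    study_ids = [f"{study_prefix}{s}" for s in range(config.n_studies)]
    batch = rng.normal(0.0, config.batch_sd, size=(config.n_studies, n_genes))
    n_modules = max(config.n_modules, 1)
    # which modules' age programs each study expresses; a module inactive
    # in a study contributes no age trend there (study-specific programs)
    activity = (
        rng.random((config.n_studies, n_modules)) < config.module_study_activity
    ).astype(float)

    gene_activity = np.ones((config.n_studies, n_genes))
    in_module = params.modules >= 0
    gene_activity[:, in_module] = activity[:, params.modules[in_module]]

    blocks: list[sp.csr_matrix] = []
    meta_rows: list[pd.DataFrame] = []
    for s, study in enumerate(study_ids):
        # study-level compositional batch effect: laboratories enrich or
        # deplete classes (dissection, dissociation, FACS), independent of age
        study_comp_offset = (
            rng.normal(0.0, config.composition_study_sd, len(BROAD_CLASSES))
            if config.composition_study_sd > 0
            else np.zeros(len(BROAD_CLASSES))
        )
        for stable in config.composition_stable_classes:
            study_comp_offset[BROAD_CLASSES.index(stable)] = 0.0
        for j, age in enumerate(config.ages):
            sample = f"{study}_s{j}"
            props = config.class_proportions(age)
            pvec = np.clip([props[c] for c in BROAD_CLASSES], 0.0, None)
            pvec = pvec * np.exp(study_comp_offset)
            if config.composition_noise_sd > 0:
                # inter-sample (donor/dissection-level) compositional
                # variability around the expected curves, independent per
                # class; stable classes are exempt
                jitter = rng.normal(0.0, config.composition_noise_sd, len(pvec))
                for stable in config.composition_stable_classes:
                    jitter[BROAD_CLASSES.index(stable)] = 0.0
                pvec = pvec * np.exp(jitter)
            pvec = pvec / pvec.sum()
            class_counts = rng.multinomial(config.cells_per_sample, pvec)
            module_factors = rng.normal(0.0, config.module_sd, size=max(config.n_modules, 1))
            module_term = np.where(params.modules >= 0, module_factors[np.clip(params.modules, 0, None)], 0.0)

            sample_cells = []
            sample_classes = []
            for c, n_c in zip(BROAD_CLASSES, class_counts):
                if n_c == 0:
                    continue
                log_rate = (
                    params.baselines
                    + params.class_profiles[class_index[c]]
                    + batch[s]
                    + module_term
                )
                if config.signal_class is None or c == config.signal_class:
                    # program anchored at age_center: baselines describe
                    # mid-development expression, and a class without the
                    # program looks like an age_center sample
                    log_rate = log_rate + params.slopes * gene_activity[s] * (
                        age * config.tempo_factor - config.age_center
                    )
                if config.noise_sd > 0:
                    logits = log_rate[None, :] + rng.normal(0.0, config.noise_sd, size=(n_c, n_genes))
                else:
                    logits = np.repeat(log_rate[None, :], n_c, axis=0)
                logits = logits - logits.max(axis=1, keepdims=True)
                probs = np.exp(logits)
                probs /= probs.sum(axis=1, keepdims=True)
                depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1, size=n_c)
                counts = np.empty((n_c, n_genes), dtype=np.int64)
                for i in range(n_c):
                    counts[i] = rng.multinomial(depths[i], probs[i])
                sample_cells.append(counts)
                sample_classes.extend([c] * n_c)
            counts_block = np.concatenate(sample_cells, axis=0)
            blocks.append(sp.csr_matrix(counts_block.T))
            meta_rows.append(
                pd.DataFrame(
                    {
                        "study_id": study,
                        "sample_id": sample,
                        "age_pcw": float(age),
                        "author_cell_type": sample_classes,
                        "broad_class": sample_classes,
                    }
                )
            )

    counts = sp.hstack(blocks, format="csr")
    cells = pd.concat(meta_rows, ignore_index=True)
    cells.insert(0, "cell_id", [f"{sid}_c{i}" for i, sid in enumerate(cells["sample_id"])])
    cells["species"] = config.species
    dataset = MultiStudyDataset(
        counts=counts,
        genes=_gene_names(n_genes),
        cells=cells,
        species=config.species,
    )
    batch_df = pd.DataFrame(batch, index=study_ids, columns=dataset.genes)
    activity_df = pd.DataFrame(
        activity, index=study_ids, columns=[f"module{m}" for m in range(n_modules)]
    )
    return dataset, batch_df, activity_df


def simulate_multistudy(config: SimulationConfig) -> tuple[MultiStudyDataset, SyntheticTruth]:
    """Generate a multi-study dataset plus its generative truth.

    The same config (including ``seed``) always yields byte-identical
    output.  Per-cell counts are multinomial over genes with probabilities
    softmax(baseline + slope * age * tempo + class profile + batch +
    module factor + noise) and library size uniform over ``depth_range``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    params = _draw_gene_params(config, rng)
    dataset, batch_df, activity_df = _simulate_counts(config, params, rng)
    truth = SyntheticTruth(
        gene_slopes=params.slopes.copy(),
        gene_module=params.modules.copy(),
        class_proportion_curves=config.class_proportions,
        tempo_factor=config.tempo_factor,
        study_batch_effects=batch_df,
        module_study_activity=activity_df,
        baselines=params.baselines.copy(),
        class_profiles=pd.DataFrame(params.class_profiles, index=list(BROAD_CLASSES), columns=dataset.genes),
        config=config,
    )
    return dataset, truth


def simulate_cross_species(
    config: SimulationConfig,
    tempo_factor_b: float,
    ortholog_fraction: float = 1.0,
    species_b: str = "mouse",
) -> tuple[MultiStudyDataset, MultiStudyDataset, OrthologMap, SyntheticTruth]:
    """Simulate two species sharing gene programs but differing in tempo.

    Species B runs the same transcriptional programs at ``tempo_factor_b``
    times the speed of species A: a species-B cell of actual age ``a``
    weeks expresses the program of species-A age ``a * tempo_factor_b``.
    Species-B sample ages are the species-A ages divided by
    ``tempo_factor_b`` so both species traverse the same program range.

    ``ortholog_fraction`` of genes are linked one-to-one in the returned
    :class:`OrthologMap`; the remainder are unmapped.  The returned truth
    is that of species A (slopes, modules, composition curves).
    """
    if tempo_factor_b <= 0:
        raise ValueError("tempo_factor_b must be > 0")
    if not (0 < ortholog_fraction <= 1):
        raise ValueError("ortholog_fraction must be in (0, 1]")
    config.validate()
    rng = np.random.default_rng(config.seed)
    params = _draw_gene_params(config, rng)

    dataset_a, batch_a, activity_a = _simulate_counts(config, params, rng, study_prefix=f"{config.species}_study")

    config_b = replace(
        config,
        ages=tuple(a / tempo_factor_b for a in config.ages),
        tempo_factor=config.tempo_factor * tempo_factor_b,
        species=species_b,
    )
    # composition curves are expressed on the species-A age axis; rescale
    # midpoints/steepness so species B shows the same compositional arc
    # over its (shorter) clock.
    curves_b = {
        c: CompositionCurve(
            midpoint=cv.midpoint / tempo_factor_b,
            steepness=cv.steepness * tempo_factor_b,
            floor=cv.floor,
            ceiling=cv.ceiling,
        )
        for c, cv in config.composition_params.items()
    }
    config_b = replace(config_b, composition_params=curves_b)
    dataset_b, _, _ = _simulate_counts(config_b, params, rng, study_prefix=f"{species_b}_study")
    dataset_b.genes = [f"{species_b}_{g}" for g in dataset_b.genes]

    n_mapped = int(round(ortholog_fraction * config.n_genes))
    mapped_idx = np.sort(rng.choice(config.n_genes, size=n_mapped, replace=False))
    records = pd.DataFrame(
        {
            "gene_a": [dataset_a.genes[i] for i in mapped_idx],
            "gene_b": [dataset_b.genes[i] for i in mapped_idx],
            "orthogroup": [f"OG{i:05d}" for i in mapped_idx],
        }
    )
    ortholog_map = OrthologMap(records=records, mode="one_to_one")

    truth = SyntheticTruth(
        gene_slopes=params.slopes.copy(),
        gene_module=params.modules.copy(),
        class_proportion_curves=config.class_proportions,
        tempo_factor=config.tempo_factor,
        study_batch_effects=batch_a,
        module_study_activity=activity_a,
        baselines=params.baselines.copy(),
        class_profiles=pd.DataFrame(params.class_profiles, index=list(BROAD_CLASSES), columns=dataset_a.genes),
        config=config,
    )
    return dataset_a, dataset_b, ortholog_map, truth


def write_fixture(dataset: MultiStudyDataset, directory: str | os.PathLike) -> dict[str, str]:
    """Write a dataset as MatrixMarket counts plus TSV metadata.

    Emits ``matrix.mtx`` (genes x cells, coordinate integer),
    ``genes.tsv`` (one identifier per row) and ``cells.tsv``.  The triple
    round-trips losslessly through :func:`read_fixture`.
    """
    if dataset.n_genes == 0 or dataset.n_cells == 0:
        raise ValueError("refusing to write an empty dataset")
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {
        "matrix": os.path.join(directory, "matrix.mtx"),
        "genes": os.path.join(directory, "genes.tsv"),
        "cells": os.path.join(directory, "cells.tsv"),
    }
    coo = dataset.counts.tocoo()
    scipy.io.mmwrite(paths["matrix"], coo, field="integer")
    with open(paths["genes"], "w") as fh:
        fh.write("\n".join(dataset.genes) + "\n")
    cells = dataset.cells.copy()
    if "species" not in cells:
        cells["species"] = dataset.species
    cells[list(CELLS_TSV_COLUMNS)].to_csv(paths["cells"], sep="\t", index=False)
    return paths


def read_fixture(directory: str | os.PathLike) -> MultiStudyDataset:
    """Read a dataset written by :func:`write_fixture` (or any .mtx+TSV triple)."""
    directory = str(directory)
    counts = sp.csr_matrix(scipy.io.mmread(os.path.join(directory, "matrix.mtx")))
    counts = counts.astype(np.int64)
    with open(os.path.join(directory, "genes.tsv")) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    cells = pd.read_csv(os.path.join(directory, "cells.tsv"), sep="\t")
    species = cells["species"].iloc[0] if "species" in cells and len(cells) else "unknown"
    return MultiStudyDataset(counts=counts, genes=genes, cells=cells, species=str(species))
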