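"""Regularized transcriptomic age predictors ("clocks").

A clock is an elastic-net regression of developmental age (pcw) on
pseudobulk gene expression, trained jointly across studies.  Observation
weights give every study equal total weight, split equally across the
broad cell classes present in that study, so large studies or abundant
classes cannot dominate the meta-analytic fit.  Predictors are
standardized internally; coefficients are stored on the standardized
scale together with per-gene training means/scales, so genes missing at
prediction time are implicitly imputed at the training mean.

Validation follows the held-out-context scheme: leave-study-out measures
cross-laboratory generalization, leave-cell-type-out measures
independence from cell identity.
"""

from __future__ import annotations

import hashlib
import logging
import os
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from devclock.aggregate import PseudobulkMatrix, pseudobulk
from devclock.simulate import MultiStudyDataset

logger = logging.getLogger(__name__)


@dataclass
class Metrics:
    """Prediction-quality summary: MAE and median AE in pcw."""

    mae: float
    median_ae: float
    pearson_r: float  # NaN when undefined (constant predictions)
    n: int
    r_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "median_ae": self.median_ae,
            "pearson_r": self.pearson_r,
            "n": self.n,
            "r_defined": self.r_defined,
        }


@dataclass
class AgeModel:
    """Serialized linear age predictor.

    Prediction for a group with expression vector x (model universe
    order) is ``intercept + sum_g coef_std[g] * (x[g] - mean[g]) / scale[g]``.
    ``alpha`` is the elastic-net mixing parameter (1 = lasso, 0 = ridge)
    and ``lambda_`` the regularization strength, both in the glmnet
    parameterization.
    """

    genes: list[str]
    coef_std: np.ndarray
    gene_mean: np.ndarray
    gene_scale: np.ndarray
    intercept: float
    normalization: str
    alpha: float
    lambda_: float
    scope: str = "agnostic"
    weighting: str = "study_class_equal"
    restriction: str | None = None

    def __post_init__(self) -> None:
        n = len(self.genes)
        for name in ("coef_std", "gene_mean", "gene_scale"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per universe gene")

    @property
    def coef_input_scale(self) -> np.ndarray:
        """Coefficients on the (normalized-expression) input scale."""
        return self.coef_std / self.gene_scale

    @property
    def intercept_input_scale(self) -> float:
        return float(self.intercept - np.sum(self.coef_std * self.gene_mean / self.gene_scale))

    @property
    def nonzero_genes(self) -> list[str]:
        return [g for g, c in zip(self.genes, self.coef_std) if c != 0.0]

    @property
    def coefficients(self) -> dict[str, float]:
        """Sparse gene -> input-scale coefficient map (nonzero only)."""
        ci = self.coef_input_scale
        return {g: float(c) for g, c in zip(self.genes, ci) if c != 0.0}

    def universe_hash(self) -> str:
        return hashlib.sha256("\n".join(self.genes).encode()).hexdigest()[:16]

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"# intercept\t{float(self.intercept)!r}\n")
            fh.write(f"# alpha\t{float(self.alpha)!r}\n")
            fh.write(f"# lambda\t{float(self.lambda_)!r}\n")
            fh.write(f"# normalization\t{self.normalization}\n")
            fh.write(f"# scope\t{self.scope}\n")
            fh.write(f"# weighting\t{self.weighting}\n")
            fh.write(f"# restriction\t{self.restriction or ''}\n")
            fh.write(f"# universe_hash\t{self.universe_hash()}\n")
            fh.write("gene\tcoef_std\tmean\tscale\n")
            for g, c, m, s in zip(self.genes, self.coef_std, self.gene_mean, self.gene_scale):
                fh.write(f"{g}\t{float(c)!r}\t{float(m)!r}\t{float(s)!r}\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "AgeModel":
        header: dict[str, str] = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# "):
                    key, _, val = line[2:].partition("\t")
                    header[key] = val
                elif line and not line.startswith("gene\t"):
                    rows.append(line.split("\t"))
        genes = [r[0] for r in rows]
        return cls(
            genes=genes,
            coef_std=np.array([float(r[1]) for r in rows]),
            gene_mean=np.array([float(r[2]) for r in rows]),
            gene_scale=np.array([float(r[3]) for r in rows]),
            intercept=float(header["intercept"]),
            normalization=header["normalization"],
            alpha=float(header["alpha"]),
            lambda_=float(header["lambda"]),
            scope=header.get("scope", "agnostic"),
            weighting=header.get("weighting", "study_class_equal"),
            restriction=header.get("restriction") or None,
        )


def concat_pseudobulks(pseudobulks: Sequence[PseudobulkMatrix]) -> PseudobulkMatrix:
    """Column-concatenate pseudobulk matrices sharing genes and normalization."""
    if len(pseudobulks) == 0:
        raise ValueError("nothing to concatenate")
    first = pseudobulks[0]
    for pb in pseudobulks[1:]:
        if pb.genes != first.genes:
            raise ValueError("gene lists differ; intersect and align first")
        if pb.normalization != first.normalization:
            raise ValueError("normalization mismatch")
    return PseudobulkMatrix(
        values=np.concatenate([pb.values for pb in pseudobulks], axis=1),
        genes=list(first.genes),
        groups=pd.concat([pb.groups for pb in pseudobulks], ignore_index=True),
        normalization=first.normalization,
    )


def study_class_weights(groups: pd.DataFrame) -> np.ndarray:
    """Observation weights: studies equal, classes equal within study.

    Each study receives total weight 1/n_studies; within a study each
    broad class present receives an equal share, split equally over its
    groups.  Without class labels, groups within a study share equally.
    Weights are rescaled to mean 1.
    """
    w = np.empty(len(groups), dtype=float)
    studies = groups["study_id"].to_numpy()
    n_studies = len(pd.unique(studies))
    has_class = "broad_class" in groups.columns
    for study in pd.unique(studies):
        in_study = studies == study
        if has_class:
            classes = groups.loc[in_study, "broad_class"].to_numpy()
            n_classes = len(pd.unique(classes))
            for cls in pd.unique(classes):
                sel = in_study & (groups["broad_class"].to_numpy() == cls)
                w[sel] = 1.0 / (n_studies * n_classes * sel.sum())
        else:
            w[in_study] = 1.0 / (n_studies * in_study.sum())
    return w / w.mean()


def _fit_enet_std(
    Z: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray,
    mixing: float,
    lam: float,
) -> tuple[np.ndarray, float]:
    """Elastic net on pre-standardized predictors (glmnet parameterization).

    Returns (coef, intercept).  The ridge limit (mixing = 0) is solved in
    closed form: coef = (Z'WZ + n*lam*I)^-1 Z'W(y - wmean(y)).
    """
    if mixing == 0.0:
        w = sample_weight / sample_weight.sum()
        ybar = float(np.sum(w * y))
        Zc = Z - np.sum(w[:, None] * Z, axis=0)
        yc = y - ybar
        n = Z.shape[0]
        A = (Zc * (w * n)[:, None]).T @ Zc / n + lam * np.eye(Z.shape[1])
        b = (Zc * (w * n)[:, None]).T @ yc / n
        coef = np.linalg.solve(A, b)
        intercept = ybar - float(np.sum(np.sum(w[:, None] * Z, axis=0) * coef))
        return coef, intercept
    model = ElasticNet(alpha=lam, l1_ratio=mixing, fit_intercept=True, max_iter=20_000, tol=1e-5)
    with warnings.catch_warnings():
        # the weakly regularized end of a CV grid may not fully converge
        # on (near-)collinear inputs; those points lose the CV anyway
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Z, y, sample_weight=sample_weight)
    return model.coef_.copy(), float(model.intercept_)


def _enet_path(
    Z: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray,
    mixing: float,
    lams: np.ndarray,
) -> list[tuple[np.ndarray, float]]:
    """Warm-started elastic-net path over a descending lambda grid."""
    if mixing == 0.0:
        return [_fit_enet_std(Z, y, sample_weight, mixing, lam) for lam in lams]
    model = ElasticNet(
        alpha=float(lams[0]), l1_ratio=mixing, fit_intercept=True,
        max_iter=20_000, tol=1e-5, warm_start=True,
    )
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for lam in lams:
            model.set_params(alpha=float(lam))
            model.fit(Z, y, sample_weight=sample_weight)
            out.append((model.coef_.copy(), float(model.intercept_)))
    return out


def _lambda_grid(Z: np.ndarray, y: np.ndarray, w: np.ndarray, mixing: float, n_lambda: int) -> np.ndarray:
    wn = w / w.sum()
    yc = y - np.sum(wn * y)
    grad = np.abs((Z * wn[:, None]).T @ yc)
    lam_max = grad.max() / max(mixing, 1e-3)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * 1e-3, n_lambda)


def train_clock(
    pseudobulks: PseudobulkMatrix | Sequence[PseudobulkMatrix],
    scope: str = "agnostic",
    alpha: float = 0.1,
    lambda_policy: float | str = "auto",
    weights: str | np.ndarray = "study_class_equal",
    n_lambda: int = 30,
    internal_cv_folds: int = 3,
    seed: int = 0,
) -> AgeModel:
    """Train an elastic-net age clock on pseudobulk expression.

    ``lambda_policy`` is either a fixed regularization strength or
    ``"auto"``: a geometric grid of ``n_lambda`` values is scored by
    internal K-fold cross-validation minimizing MAE and the sparsest
    lambda within the minimum is kept.  ``weights`` defaults to the
    study-equal/class-equal scheme of :func:`study_class_weights`.
    """
    pb = pseudobulks if isinstance(pseudobulks, PseudobulkMatrix) else concat_pseudobulks(list(pseudobulks))
    y = pb.groups["age_pcw"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("constant response: need >= 2 distinct ages")
    X = pb.values.T  # groups x genes

    if isinstance(weights, str):
        if weights != "study_class_equal":
            raise ValueError(f"unknown weighting scheme {weights!r}")
        w = study_class_weights(pb.groups)
        weighting_id = "study_class_equal"
    else:
        w = np.asarray(weights, dtype=float)
        weighting_id = "custom"

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    Z = (X - mean) / scale

    if lambda_policy == "auto":
        grid = _lambda_grid(Z, y, w, alpha, n_lambda)
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(y))
        folds = np.array_split(order, min(internal_cv_folds, len(y)))
        cv_mae = np.zeros(len(grid))
        for fold in folds:
            mask = np.ones(len(y), dtype=bool)
            mask[fold] = False
            if len(np.unique(y[mask])) < 2:
                raise ValueError("degenerate internal CV fold (single age)")
            path = _enet_path(Z[mask], y[mask], w[mask], alpha, grid)
            for k, (coef, icept) in enumerate(path):
                pred = Z[fold] @ coef + icept
                cv_mae[k] += np.mean(np.abs(pred - y[fold])) / len(folds)
        best = np.min(cv_mae)
        lam = float(grid[np.flatnonzero(cv_mae <= best + 1e-12)[0]])  # grid descends: first = sparsest
    else:
        lam = float(lambda_policy)
        if lam <= 0:
            raise ValueError("lambda must be > 0")

    coef, intercept = _fit_enet_std(Z, y, w, alpha, lam)
    return AgeModel(
        genes=list(pb.genes),
        coef_std=coef,
        gene_mean=mean,
        gene_scale=scale,
        intercept=intercept,
        normalization=pb.normalization,
        alpha=alpha,
        lambda_=lam,
        scope=scope,
        weighting=weighting_id,
    )


def predict_age(model: AgeModel, pb: PseudobulkMatrix, min_coverage: float = 0.5) -> pd.DataFrame:
    """Predict age for every pseudobulk group.

    The pseudobulk normalization must match the model's (hard error).
    Model genes absent from the input contribute zero on the
    standardized scale (training-mean imputation); the coverage fraction
    of nonzero-coefficient genes present is logged and must reach
    ``min_coverage``.
    """
    if pb.normalization != model.normalization:
        raise ValueError(
            f"normalization mismatch: model={model.normalization!r}, input={pb.normalization!r}"
        )
    index = {g: i for i, g in enumerate(pb.genes)}
    nz = model.nonzero_genes
    if len(nz) == 0:
        covered = 1.0
    else:
        covered = sum(g in index for g in nz) / len(nz)
    logger.info("predict_age: %.1f%% of model genes covered", 100 * covered)
    if covered < min_coverage:
        raise ValueError(f"only {covered:.0%} of model genes present (min {min_coverage:.0%})")

    pred = np.full(pb.n_groups, model.intercept, dtype=float)
    for j, g in enumerate(model.genes):
        c = model.coef_std[j]
        if c == 0.0 or g not in index:
            continue
        x = pb.values[index[g]]
        pred += c * (x - model.gene_mean[j]) / model.gene_scale[j]

    out = pb.groups.copy()
    out["predicted_age_pcw"] = pred
    return out


def evaluate(predictions: pd.DataFrame) -> Metrics:
    """MAE, median AE and Pearson r of predicted vs true age."""
    if len(predictions) == 0:
        raise ValueError("empty predictions")
    err = predictions["predicted_age_pcw"].to_numpy() - predictions["age_pcw"].to_numpy()
    y = predictions["age_pcw"].to_numpy()
    p = predictions["predicted_age_pcw"].to_numpy()
    r_defined = np.std(p) > 0 and np.std(y) > 0 and len(y) > 1
    r = float(stats.pearsonr(y, p).statistic) if r_defined else float("nan")
    if not r_defined:
        logger.warning("Pearson r undefined (constant predictions or ages)")
    return Metrics(
        mae=float(np.mean(np.abs(err))),
        median_ae=float(np.median(np.abs(err))),
        pearson_r=r,
        n=len(err),
        r_defined=bool(r_defined),
    )


def _held_out_cv(
    pb: PseudobulkMatrix,
    by: str,
    trainer: Callable[[PseudobulkMatrix], AgeModel],
) -> tuple[pd.DataFrame, pd.DataFrame, Metrics]:
    labels = pb.groups[by].to_numpy()
    unique = pd.unique(labels)
    if len(unique) < 2:
        raise ValueError(f"need >= 2 distinct {by} values for held-out CV")
    preds = []
    fold_rows = []
    for fold_id, held in enumerate(unique):
        test_mask = labels == held
        train_pb = pb.subset_groups(~test_mask)
        if train_pb.n_groups == 0:
            raise ValueError(f"empty training set for fold {held!r}")
        model = trainer(train_pb)
        fold_pred = predict_age(model, pb.subset_groups(test_mask))
        fold_pred["fold_id"] = str(held)
        m = evaluate(fold_pred)
        fold_rows.append({"fold_id": str(held), **m.as_dict()})
        preds.append(fold_pred)
    predictions = pd.concat(preds, ignore_index=True)
    return predictions, pd.DataFrame(fold_rows), evaluate(predictions)


def leave_study_out_cv(
    pb: PseudobulkMatrix,
    trainer: Callable[[PseudobulkMatrix], AgeModel] | None = None,
    **train_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, Metrics]:
    """Predict every study once from a model trained on all the others."""
    trainer = trainer or (lambda train_pb: train_clock(train_pb, **train_kwargs))
    return _held_out_cv(pb, "study_id", trainer)


def leave_celltype_out_cv(
    pb: PseudobulkMatrix,
    trainer: Callable[[PseudobulkMatrix], AgeModel] | None = None,
    **train_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, Metrics]:
    """Predict every broad class once from a model trained on the others."""
    if "broad_class" not in pb.groups:
        raise ValueError("pseudobulk lacks broad_class labels")
    trainer = trainer or (lambda train_pb: train_clock(train_pb, **train_kwargs))
    return _held_out_cv(pb, "broad_class", trainer)


def train_class_specific(pb: PseudobulkMatrix, broad_class: str, **train_kwargs) -> AgeModel:
    """Train a clock only on one broad class's pseudobulks.

    The returned model can be evaluated on any class (cross-class
    application) with :func:`predict_age`.
    """
    if "broad_class" not in pb.groups:
        raise ValueError("pseudobulk lacks broad_class labels")
    mask = pb.groups["broad_class"].to_numpy() == broad_class
    if not mask.any():
        raise ValueError(f"class {broad_class!r} absent")
    if pb.groups.loc[mask, "study_id"].nunique() < 2:
        raise ValueError(f"class {broad_class!r} present in < 2 studies")
    model = train_clock(pb.subset_groups(mask), scope=f"class-specific:{broad_class}", **train_kwargs)
    return model


def restrict_and_train(pb: PseudobulkMatrix, gene_set: Sequence[str], restriction_id: str | None = None, **train_kwargs) -> AgeModel:
    """Train a clock restricted to a gene set (e.g. one GO term)."""
    present = [g for g in pb.genes if g in set(gene_set)]
    if len(present) == 0:
        raise ValueError("gene set does not intersect the pseudobulk universe")
    model = train_clock(pb.subset_genes(present), **train_kwargs)
    model.restriction = restriction_id or f"set:{len(present)}genes"
    return model


def evaluate_gene_sets(
    pb: PseudobulkMatrix,
    gene_sets: dict[str, Sequence[str]],
    **train_kwargs,
) -> pd.DataFrame:
    """Leave-study-out metrics for a batch of gene-set-restricted clocks."""
    rows = []
    for name, genes in gene_sets.items():
        present = [g for g in pb.genes if g in set(genes)]
        if not present:
            logger.warning("gene set %s has no overlap; skipped", name)
            continue
        sub = pb.subset_genes(present)
        _, _, pooled = leave_study_out_cv(sub, **train_kwargs)
        rows.append({"gene_set": name, "n_genes": len(present), **pooled.as_dict()})
    return pd.DataFrame(rows)


def subsample_robustness(
    dataset: MultiStudyDataset,
    n_models: int,
    cells_per_group: int,
    seed: int = 0,
    normalization: str = "lognorm",
    **train_kwargs,
) -> pd.DataFrame:
    """Held-out performance of clocks trained on subsampled cells.

    For each of ``n_models`` replicates, every (sample x class) group is
    subsampled to ``cells_per_group`` cells without replacement before
    aggregation, and a leave-study-out CV is run on the result.  Groups
    smaller than ``cells_per_group`` raise, so replicates are trained on
    exactly comparable cell numbers.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    cells = dataset.cells
    group_sizes = cells.groupby(["study_id", "sample_id", "broad_class"]).size()
    if cells_per_group > group_sizes.min():
        raise ValueError(
            f"cells_per_group={cells_per_group} exceeds smallest group ({group_sizes.min()})"
        )
    rows = []
    for m in range(n_models):
        rng = np.random.default_rng([seed, m])
        keep_idx = []
        for _, idx in cells.groupby(["study_id", "sample_id", "broad_class"]).indices.items():
            keep_idx.append(rng.choice(idx, size=cells_per_group, replace=False))
        keep = np.sort(np.concatenate(keep_idx))
        sub = dataset.subset_cells(keep)
        pb = pseudobulk(sub, group_keys="sample_class", normalization=normalization)
        _, _, pooled = leave_study_out_cv(pb, **train_kwargs)
        rows.append({"model": m, **pooled.as_dict()})
    return pd.DataFrame(rows)
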