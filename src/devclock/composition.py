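"""Age prediction from tissue composition and from expression PCs.

Three families of tissue-level predictors:

* study-specific elastic-net models on the 7 broad-class proportions,
  evaluated by leave-one-sample-out CV (accurate within a study, known
  not to generalize);
* per-study PCA models: the principal component of per-sample pseudobulk
  expression most correlated with age, with a linear score-to-age map,
  projectable onto other studies using the training study's gene
  centering/scaling; plus an ablation probe that removes one cell class
  and asks whether the age-correlated component survives;
* meta-analytic feature selection over single classes and class pairs
  (notably astrocytes rising / progenitors falling), ranked by
  leave-study-out MAE with a within-study age-permutation null.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from devclock.aggregate import PseudobulkMatrix, pseudobulk
from devclock.clock import _fit_enet_std
from devclock.simulate import BROAD_CLASSES, MultiStudyDataset

logger = logging.getLogger(__name__)


def compute_proportions(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-sample broad-class proportions.

    Returns one row per sample with study_id, sample_id, age_pcw, n_cells
    and one proportion column per broad class (summing to 1).
    """
    if "broad_class" not in cells:
        raise ValueError("cells lack broad_class; run map_cell_classes first")
    counts = (
        cells.groupby(["study_id", "sample_id", "broad_class"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(BROAD_CLASSES), fill_value=0)
    )
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("sample with zero cells")
    props = counts.div(totals, axis=0)
    meta = cells.groupby(["study_id", "sample_id"])["age_pcw"].first()
    out = props.reset_index()
    out.insert(2, "age_pcw", meta.loc[pd.MultiIndex.from_frame(out[["study_id", "sample_id"]])].to_numpy())
    out.insert(3, "n_cells", totals.to_numpy())
    return out


@dataclass
class StudyCompositionModel:
    """Elastic-net age model on class proportions for one study."""

    study_id: str
    coefficients: pd.Series  # per broad class, input scale
    intercept: float
    alpha: float
    lambda_: float
    loocv_predictions: pd.DataFrame
    mae: float

    def predict(self, proportions: pd.DataFrame) -> np.ndarray:
        X = proportions[list(BROAD_CLASSES)].to_numpy(dtype=float)
        return self.intercept + X @ self.coefficients.to_numpy()


def _fit_enet_grid(
    X: np.ndarray,
    y: np.ndarray,
    alphas=(0.1, 0.5, 1.0),
    n_lambda: int = 20,
) -> tuple[np.ndarray, float, float, float]:
    """Small elastic-net grid scored by LOOCV MAE on (X, y).

    The winning (alpha, lambda) follows the one-standard-error rule: the
    most regularized pair whose LOOCV MAE is within one SE of the
    minimum, so pure-noise predictors fall back to the null (mean-age)
    model instead of overfitting.  Returns (coef, intercept, alpha,
    lambda) refit on all rows, coefficients on the input scale.
    """
    mean, scale = X.mean(axis=0), X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    Z = (X - mean) / scale
    w = np.ones(len(y))
    records = []  # (lam, mix, mean_mae, se)
    for mix in alphas:
        grad = np.abs(Z.T @ (y - y.mean())) / len(y)
        lam_max = max(grad.max() / max(mix, 1e-3), 1e-6)
        for lam in np.geomspace(lam_max * 2, lam_max * 1e-4, n_lambda):
            errs = []
            for i in range(len(y)):
                mask = np.ones(len(y), dtype=bool)
                mask[i] = False
                coef, icept = _fit_enet_std(Z[mask], y[mask], w[mask], mix, lam)
                errs.append(abs(Z[i] @ coef + icept - y[i]))
            errs = np.asarray(errs)
            records.append((lam, mix, float(errs.mean()), float(errs.std(ddof=1) / np.sqrt(len(errs)))))
    best_mae, best_se = min((r[2], r[3]) for r in records)
    eligible = [r for r in records if r[2] <= best_mae + best_se]
    lam, mix = max((r[0], r[1]) for r in eligible)
    coef, icept = _fit_enet_std(Z, y, w, mix, lam)
    coef_input = coef / scale
    icept_input = icept - float(np.sum(coef * mean / scale))
    return coef_input, icept_input, mix, lam


def fit_study_composition_model(comp: pd.DataFrame, min_timepoints: int = 4) -> StudyCompositionModel:
    """Fit one study's composition-to-age model with LOOCV.

    Requires at least ``min_timepoints`` distinct ages; studies below
    the threshold should be skipped by the caller (see
    :func:`fit_all_study_composition_models`).
    """
    studies = comp["study_id"].unique()
    if len(studies) != 1:
        raise ValueError("expected a single study's composition table")
    study = str(studies[0])
    y = comp["age_pcw"].to_numpy(dtype=float)
    if len(np.unique(y)) < min_timepoints:
        raise ValueError(f"study {study}: fewer than {min_timepoints} distinct time points")
    X = comp[list(BROAD_CLASSES)].to_numpy(dtype=float)

    coef, icept, mix, lam = _fit_enet_grid(X, y)

    # leave-one-sample-out predictions; hyperparameter selection is nested
    # inside each fold so the held-out label never influences its own
    # prediction
    preds = np.empty(len(y))
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        c_i, ic_i, _, _ = _fit_enet_grid(X[mask], y[mask])
        preds[i] = X[i] @ c_i + ic_i
    loocv = comp[["study_id", "sample_id", "age_pcw"]].copy()
    loocv["predicted_age_pcw"] = preds
    loocv["fold_id"] = loocv["sample_id"]
    mae = float(np.mean(np.abs(preds - y)))
    return StudyCompositionModel(
        study_id=study,
        coefficients=pd.Series(coef, index=list(BROAD_CLASSES)),
        intercept=icept,
        alpha=mix,
        lambda_=lam,
        loocv_predictions=loocv,
        mae=mae,
    )


def fit_all_study_composition_models(comp: pd.DataFrame, min_timepoints: int = 4) -> dict[str, StudyCompositionModel]:
    """Fit every eligible study, skipping (with a log entry) those with
    too few distinct time points."""
    models = {}
    for study, sub in comp.groupby("study_id"):
        try:
            models[str(study)] = fit_study_composition_model(sub, min_timepoints)
        except ValueError as exc:
            logger.info("skipping study %s: %s", study, exc)
    return models


@dataclass
class PCAgeModel:
    """Per-study PCA age model: one age-correlated component + linear map."""

    study_id: str
    genes: list[str]
    gene_mean: np.ndarray
    gene_scale: np.ndarray
    loading: np.ndarray  # unit norm
    component: int  # 0-based index of the selected PC
    slope: float
    intercept: float
    r: float
    p_value: float
    pc_age_correlations: np.ndarray  # |r| of every computed component
    significant: bool = True

    def score(self, pb: PseudobulkMatrix, min_gene_overlap: float = 0.5) -> np.ndarray:
        index = {g: i for i, g in enumerate(pb.genes)}
        present = [g in index for g in self.genes]
        frac = np.mean(present)
        if frac < min_gene_overlap:
            raise ValueError(f"only {frac:.0%} of training genes present (min {min_gene_overlap:.0%})")
        Z = np.zeros((pb.n_groups, len(self.genes)))
        for j, g in enumerate(self.genes):
            if g in index:
                Z[:, j] = (pb.values[index[g]] - self.gene_mean[j]) / self.gene_scale[j]
        return Z @ self.loading

    def predict(self, pb: PseudobulkMatrix) -> pd.DataFrame:
        out = pb.groups.copy()
        out["predicted_age_pcw"] = self.slope * self.score(pb) + self.intercept
        return out


def fit_pc_age_model(pb: PseudobulkMatrix, npcs: int = 5, p_threshold: float = 0.05) -> PCAgeModel:
    """PCA of per-sample pseudobulk; select the age-correlated component.

    Genes are centered and unit-scaled on the training study.  Among the
    top ``npcs`` components (capped at the matrix rank), the one with the
    largest |Pearson r| against sample age is kept and a least-squares
    line maps its score to age.  A non-significant best correlation is
    flagged rather than rejected.
    """
    y = pb.groups["age_pcw"].to_numpy(dtype=float)
    if pb.n_groups < 3:
        raise ValueError("need >= 3 samples for a PC age model")
    X = pb.values.T  # samples x genes
    mean, scale = X.mean(axis=0), X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    Z = (X - mean) / scale
    rank = min(pb.n_groups - 1, Z.shape[1])
    k = min(npcs, rank)
    if k < npcs:
        logger.info("npcs capped at rank %d", k)
    U, S, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    scores = U[:, :k] * S[:k]
    corrs = np.zeros(k)
    pvals = np.ones(k)
    for j in range(k):
        if np.std(scores[:, j]) > 0:
            res = stats.pearsonr(scores[:, j], y)
            corrs[j], pvals[j] = res.statistic, res.pvalue
    best = int(np.argmax(np.abs(corrs)))
    sc = scores[:, best]
    if np.std(sc) > 0:
        slope, intercept = np.polyfit(sc, y, 1)
    else:  # degenerate (constant) expression: fall back to the mean age
        slope, intercept = 0.0, float(np.mean(y))
    study = str(pb.groups["study_id"].iloc[0]) if "study_id" in pb.groups else "unknown"
    return PCAgeModel(
        study_id=study,
        genes=list(pb.genes),
        gene_mean=mean,
        gene_scale=scale,
        loading=Vt[best].copy(),
        component=best,
        slope=float(slope),
        intercept=float(intercept),
        r=float(corrs[best]),
        p_value=float(pvals[best]),
        pc_age_correlations=np.abs(corrs),
        significant=bool(pvals[best] < p_threshold),
    )


def project_pc_model(model: PCAgeModel, pb: PseudobulkMatrix) -> pd.DataFrame:
    """Project another study onto the model's age-correlated PC.

    Test pseudobulk is centered/scaled with the *training* parameters;
    genes absent from the test study contribute zero to the score
    (training-mean imputation).  At least half of the training genes must
    be present.
    """
    return model.predict(pb)


def pc_ablation(
    dataset: MultiStudyDataset,
    class_to_remove: str,
    npcs: int = 5,
    normalization: str = "lognorm",
) -> dict:
    """Remove one broad class, recompute per-sample PCs, compare age |r|.

    Returns the per-component |r(age)| profiles before and after removal
    and whether the age-correlated component index changed.
    """
    cells = dataset.cells
    if class_to_remove not in set(cells["broad_class"]):
        logger.info("class %r absent: ablation is a no-op", class_to_remove)
    keep = cells["broad_class"].to_numpy() != class_to_remove
    emptied = set(cells["sample_id"]) - set(cells.loc[keep, "sample_id"])
    if emptied:
        raise ValueError(f"removing {class_to_remove!r} empties samples: {sorted(emptied)[:3]}")
    before_pb = pseudobulk(dataset, group_keys="sample", normalization=normalization)
    before = fit_pc_age_model(before_pb, npcs=npcs)
    after_pb = pseudobulk(dataset.subset_cells(keep), group_keys="sample", normalization=normalization)
    after = fit_pc_age_model(after_pb, npcs=npcs)
    return {
        "class_removed": class_to_remove,
        "before_abs_r": before.pc_age_correlations,
        "after_abs_r": after.pc_age_correlations,
        "component_before": before.component,
        "component_after": after.component,
        "argmax_changed": before.component != after.component,
    }


def _ols_predict(X_train, y_train, X_test) -> np.ndarray:
    A = np.column_stack([np.ones(len(X_train)), X_train])
    beta, *_ = np.linalg.lstsq(A, y_train, rcond=None)
    return np.column_stack([np.ones(len(X_test)), X_test]) @ beta


def _loso_mae(comp: pd.DataFrame, features: tuple[str, ...], ages: np.ndarray) -> float:
    X = comp[list(features)].to_numpy(dtype=float)
    studies = comp["study_id"].to_numpy()
    maes = []
    for study in pd.unique(studies):
        test = studies == study
        pred = _ols_predict(X[~test], ages[~test], X[test])
        maes.append(float(np.mean(np.abs(pred - ages[test]))))
    return float(np.mean(maes))


@dataclass
class CompositionFeatureSelection:
    """Meta-analytic composition feature-selection result."""

    ranking: pd.DataFrame  # features, mean leave-study-out MAE, rank
    best_features: tuple[str, ...]
    coefficients: pd.Series  # refit on all studies, includes intercept
    permutation_p: float
    n_permutations: int
    loso_predictions: pd.DataFrame


def select_composition_features(
    comp: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
) -> CompositionFeatureSelection:
    """Rank class singletons and pairs by leave-study-out MAE.

    Ordinary least-squares models are fit on every single broad class and
    every pair of classes; candidates are ranked by mean held-out-study
    MAE.  The best set is refit on all studies and its significance is
    assessed against a null of ages permuted within study:
    p = (1 + #null runs with MAE <= observed) / (1 + n_permutations).
    """
    if comp["study_id"].nunique() < 3:
        raise ValueError("need >= 3 studies for meta-analytic feature selection")
    ages = comp["age_pcw"].to_numpy(dtype=float)
    candidates = [(c,) for c in BROAD_CLASSES] + list(itertools.combinations(BROAD_CLASSES, 2))
    rows = [{"features": "+".join(f), "mean_mae": _loso_mae(comp, f, ages)} for f in candidates]
    ranking = pd.DataFrame(rows).sort_values("mean_mae", ignore_index=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    best = tuple(ranking.loc[0, "features"].split("+"))
    observed = float(ranking.loc[0, "mean_mae"])

    # refit best set on all studies
    X = comp[list(best)].to_numpy(dtype=float)
    A = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(A, ages, rcond=None)
    coefficients = pd.Series(beta, index=["intercept", *best])

    # held-out predictions with *nested* feature selection: the candidate
    # set scored for a held-out study is chosen by inner leave-study-out
    # over the remaining studies only, so a study's predictions are
    # invariant to permutations of its own age labels
    studies = comp["study_id"].to_numpy()
    preds = np.empty(len(ages))
    fold_features = {}
    for study in pd.unique(studies):
        test = studies == study
        inner = comp.loc[~test].reset_index(drop=True)
        inner_ages = inner["age_pcw"].to_numpy(dtype=float)
        inner_rank = sorted(candidates, key=lambda f: _loso_mae(inner, f, inner_ages))
        feats = inner_rank[0]
        fold_features[str(study)] = feats
        Xf = comp[list(feats)].to_numpy(dtype=float)
        preds[test] = _ols_predict(Xf[~test], ages[~test], Xf[test])
    loso = comp[["study_id", "sample_id", "age_pcw"]].copy()
    loso["predicted_age_pcw"] = preds
    loso["fold_id"] = loso["study_id"]

    rng = np.random.default_rng(seed)
    better = 0
    for _ in range(n_permutations):
        perm = ages.copy()
        for study in pd.unique(studies):
            sel = studies == study
            perm[sel] = rng.permutation(perm[sel])
        if _loso_mae(comp, best, perm) <= observed:
            better += 1
    p = (1 + better) / (1 + n_permutations)
    return CompositionFeatureSelection(
        ranking=ranking,
        best_features=best,
        coefficients=coefficients,
        permutation_p=float(p),
        n_permutations=n_permutations,
        loso_predictions=loso,
    )
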