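"""Cross-species and cross-system application of trained clocks.

Covers ortholog-restricted prediction, developmental-tempo slopes
(predicted pcw per actual week of each system's own clock), the
synchrony ANOVA between compositional and cell-autonomous ages, and the
age-difference / transcriptome-similarity AUROC statistic.

All actual ages are expressed in weeks before slope fitting; ages on
other clocks (embryonic days, days in vitro) must be divided by 7 at the
interface, so tempo slopes are weeks-per-week and a tempo ratio of r
means one system's transcriptional clock runs r times faster.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.stats import rankdata

from devclock.aggregate import PseudobulkMatrix
from devclock.clock import AgeModel
from devclock.interpret import _auroc
from devclock.simulate import OrthologMap

logger = logging.getLogger(__name__)


def apply_ortholog_map(
    obj: AgeModel | PseudobulkMatrix,
    omap: OrthologMap,
    source: str = "b",
):
    """Map a pseudobulk matrix or model across species.

    For a pseudobulk matrix, ``source`` names the species whose gene
    identifiers the matrix currently uses ("a" or "b"); one-to-one mode
    renames and subsets genes to the mapped counterparts, orthogroup mode
    averages expression across member genes per orthogroup (features are
    then orthogroup ids and any model must be retrained on them).

    For an :class:`AgeModel` (one-to-one mode only), the model universe
    is restricted to mapped genes and renamed, so the model can score the
    other species directly; coverage of nonzero genes is logged.
    """
    src = "gene_a" if source == "a" else "gene_b"
    dst = "gene_b" if source == "a" else "gene_a"
    rec = omap.records
    if len(rec) == 0:
        raise ValueError("empty ortholog map")

    if isinstance(obj, PseudobulkMatrix):
        if omap.mode == "one_to_one":
            lut = dict(zip(rec[src], rec[dst]))
            keep = [i for i, g in enumerate(obj.genes) if g in lut]
            if not keep:
                raise ValueError("no genes covered by the ortholog map")
            return PseudobulkMatrix(
                values=obj.values[keep],
                genes=[lut[obj.genes[i]] for i in keep],
                groups=obj.groups.copy(),
                normalization=obj.normalization,
            )
        # orthogroup mode: average member genes per orthogroup
        index = {g: i for i, g in enumerate(obj.genes)}
        og_rows = []
        og_ids = []
        for og, sub in rec.groupby("orthogroup", sort=True):
            members = [index[g] for g in sub[src].unique() if g in index]
            if not members:
                continue
            og_rows.append(obj.values[members].mean(axis=0))
            og_ids.append(str(og))
        if not og_rows:
            raise ValueError("no genes covered by the ortholog map")
        return PseudobulkMatrix(
            values=np.vstack(og_rows),
            genes=og_ids,
            groups=obj.groups.copy(),
            normalization=obj.normalization,
        )

    if isinstance(obj, AgeModel):
        if omap.mode != "one_to_one":
            raise ValueError("models can only be mapped with a one_to_one map; retrain on orthogroup features")
        lut = dict(zip(rec[src], rec[dst]))
        keep = [i for i, g in enumerate(obj.genes) if g in lut]
        nz = set(obj.nonzero_genes)
        covered = sum(1 for i in keep if obj.genes[i] in nz)
        if nz and covered == 0:
            raise ValueError("ortholog map covers none of the model's nonzero genes")
        logger.info("ortholog restriction keeps %d/%d nonzero model genes", covered, len(nz))
        return AgeModel(
            genes=[lut[obj.genes[i]] for i in keep],
            coef_std=obj.coef_std[keep],
            gene_mean=obj.gene_mean[keep],
            gene_scale=obj.gene_scale[keep],
            intercept=obj.intercept,
            normalization=obj.normalization,
            alpha=obj.alpha,
            lambda_=obj.lambda_,
            scope=obj.scope,
            weighting=obj.weighting,
            restriction="orthologs",
        )
    raise TypeError(f"cannot map object of type {type(obj).__name__}")


@dataclass
class TempoFit:
    """Linear fit of predicted pcw against a system's actual age (weeks)."""

    system: str
    slope: float
    intercept: float
    slope_se: float
    ci_low: float
    ci_high: float
    n: int
    r: float

    def as_dict(self) -> dict:
        return {
            "system": self.system,
            "slope": self.slope,
            "intercept": self.intercept,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "r": self.r,
        }


def tempo_slopes(predictions: pd.DataFrame, system_col: str = "system") -> dict[str, TempoFit]:
    """Per-system OLS slope of mean predicted age on actual age.

    ``predictions`` needs columns sample_id, actual_age_weeks,
    predicted_age_pcw and a system label; predictions are averaged per
    sample before fitting.  A system needs >= 3 samples and >= 2 distinct
    actual ages.
    """
    out = {}
    for system, sub in predictions.groupby(system_col):
        per_sample = sub.groupby("sample_id").agg(
            actual=("actual_age_weeks", "first"),
            predicted=("predicted_age_pcw", "mean"),
        )
        if len(per_sample) < 3:
            raise ValueError(f"system {system}: fewer than 3 samples")
        x = per_sample["actual"].to_numpy(dtype=float)
        y = per_sample["predicted"].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            raise ValueError(f"system {system}: all samples share one actual age")
        res = stats.linregress(x, y)
        tcrit = stats.t.ppf(0.975, df=len(x) - 2)
        out[str(system)] = TempoFit(
            system=str(system),
            slope=float(res.slope),
            intercept=float(res.intercept),
            slope_se=float(res.stderr),
            ci_low=float(res.slope - tcrit * res.stderr),
            ci_high=float(res.slope + tcrit * res.stderr),
            n=len(x),
            r=float(res.rvalue),
        )
    return out


def tempo_ratio(fit_a: TempoFit, fit_b: TempoFit) -> dict:
    """Ratio of tempo slopes (a over b) with a delta-method 95% CI."""
    if fit_b.slope == 0:
        raise ValueError("denominator slope is zero")
    ratio = fit_a.slope / fit_b.slope
    var = (fit_a.slope_se / fit_b.slope) ** 2 + (fit_a.slope * fit_b.slope_se / fit_b.slope**2) ** 2
    se = float(np.sqrt(var))
    return {
        "ratio": float(ratio),
        "se": se,
        "ci_low": float(ratio - 1.96 * se),
        "ci_high": float(ratio + 1.96 * se),
    }


def synchrony_anova(data: pd.DataFrame) -> pd.DataFrame:
    """Type-II ANOVA of cell-autonomous age on compositional age x system.

    ``data`` needs columns cellautonomous_age, compositional_age and
    system.  Returns the ANOVA table with F and p for the system main
    effect and the compositional-age-by-system interaction — the
    interaction tests whether the synchrony between tissue-level and
    cell-autonomous maturation differs between systems.
    """
    need = {"cellautonomous_age", "compositional_age", "system"}
    if not need.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(need)}")
    if data["system"].nunique() < 2:
        raise ValueError("need >= 2 systems")
    counts = data.groupby("system").size()
    if (counts < 3).any():
        raise ValueError("each system needs >= 3 samples")
    model = smf.ols("cellautonomous_age ~ compositional_age * C(system)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return table


def similarity_auroc(
    pb: PseudobulkMatrix,
    ages: np.ndarray | pd.Series,
    thresholds: list[float],
    stratum: str = "all",
) -> pd.DataFrame:
    """AUROC that near-in-age group pairs are more similar.

    Spearman correlations between all pseudobulk group pairs are ranked;
    for each age-difference threshold t the Mann-Whitney AUROC tests
    whether pairs with |Δage| < t have higher similarity rank than pairs
    with |Δage| >= t.  ``ages`` may be predicted or observed, so the two
    can be compared on the same pairs.  ``stratum`` restricts pairs to
    same-class or cross-class combinations.
    """
    if pb.n_groups < 4:
        raise ValueError("need >= 4 groups")
    if stratum not in ("all", "same_class", "cross_class"):
        raise ValueError(f"unknown stratum {stratum!r}")
    ages = np.asarray(ages, dtype=float)
    if len(ages) != pb.n_groups:
        raise ValueError("ages must align with pseudobulk groups")
    ranks = rankdata(pb.values, axis=0, method="average")
    sim = np.corrcoef(ranks.T)

    classes = pb.groups["broad_class"].to_numpy() if "broad_class" in pb.groups else None
    if stratum != "all" and classes is None:
        raise ValueError("class stratification requires broad_class labels")

    pair_sim, pair_diff = [], []
    for i, j in itertools.combinations(range(pb.n_groups), 2):
        if stratum == "same_class" and classes[i] != classes[j]:
            continue
        if stratum == "cross_class" and classes[i] == classes[j]:
            continue
        pair_sim.append(sim[i, j])
        pair_diff.append(abs(ages[i] - ages[j]))
    pair_sim = np.asarray(pair_sim)
    pair_diff = np.asarray(pair_diff)

    rows = []
    for t in thresholds:
        if t <= 0:
            raise ValueError("thresholds must be > 0")
        labels = pair_diff < t
        if labels.all() or not labels.any():
            raise ValueError(f"threshold {t}: one side of the split is empty")
        rows.append({"threshold": t, "auroc": _auroc(pair_sim, labels), "n_pairs": len(labels)})
    return pd.DataFrame(rows)


def compare_comp_vs_cellautonomous(
    clock_predictions: pd.DataFrame,
    comp_predictions: pd.DataFrame,
    classes: tuple[str, ...] = ("Astrocyte", "Progenitor", "Neuron"),
    system_col: str | None = None,
) -> pd.DataFrame:
    """Correlate mean cell-autonomous age with compositional age per sample.

    ``clock_predictions`` holds per-(sample x class) clock predictions;
    the cell-autonomous age of a sample is the mean over the given
    classes.  ``comp_predictions`` holds one compositional prediction per
    sample.  Returns Pearson r and p per system (or pooled).
    """
    sub = clock_predictions
    if "broad_class" in sub.columns:
        sub = sub[sub["broad_class"].isin(classes)]
    ca = sub.groupby("sample_id")["predicted_age_pcw"].mean().rename("cellautonomous_age")
    comp = comp_predictions.set_index("sample_id")["predicted_age_pcw"].rename("compositional_age")
    merged = pd.concat([ca, comp], axis=1, join="inner").dropna()
    if system_col is not None:
        systems = clock_predictions.groupby("sample_id")[system_col].first()
        merged[system_col] = systems.loc[merged.index]
        groups = merged.groupby(system_col)
    else:
        merged["_all"] = "all"
        groups = merged.groupby("_all")
    rows = []
    for system, g in groups:
        if len(g) < 3:
            raise ValueError(f"system {system}: fewer than 3 shared samples")
        res = stats.pearsonr(g["cellautonomous_age"], g["compositional_age"])
        rows.append({"system": system, "r": float(res.statistic), "p": float(res.pvalue), "n": len(g)})
    return pd.DataFrame(rows)
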