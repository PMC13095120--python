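"""Model interpretation: feature importance, age-gene discovery,
aggregate co-expression networks, module detection and enrichment.

The aggregate network follows the meta-analytic co-expression recipe:
per study, Spearman correlations between genes are computed from
pseudobulk profiles, the entries are rank-standardized into [0, 1]
(average ties), and the standardized matrices are averaged across
studies.  Module coherence is scored by neighbor voting: hide part of a
module, score every candidate gene by its (degree-normalized)
connectivity to the retained members, and summarize recovery of the
hidden members as an AUROC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from devclock.aggregate import PseudobulkMatrix
from devclock.clock import AgeModel, evaluate, predict_age, train_clock

logger = logging.getLogger(__name__)


def _auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC of scores for labels==1 vs labels==0 (midranks)."""
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC needs both classes non-empty")
    ranks = rankdata(scores, method="average")
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def permutation_importance(
    model: AgeModel,
    pb: PseudobulkMatrix,
    n_perm: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Mean MAE increase when one gene's expression is permuted.

    Each nonzero-coefficient gene is permuted across groups ``n_perm``
    times independently and the mean resulting increase in MAE is
    recorded; zero-coefficient genes are defined to have importance 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    base_pred = predict_age(model, pb)
    base_mae = evaluate(base_pred).mae
    y = pb.groups["age_pcw"].to_numpy(dtype=float)
    pred0 = base_pred["predicted_age_pcw"].to_numpy()

    index = {g: i for i, g in enumerate(pb.genes)}
    out = pd.Series(0.0, index=pd.Index(model.genes, name="gene"))
    for j, g in enumerate(model.genes):
        c = model.coef_std[j]
        if c == 0.0 or g not in index:
            continue
        x = pb.values[index[g]]
        contrib = c * (x - model.gene_mean[j]) / model.gene_scale[j]
        deltas = np.empty(n_perm)
        for t in range(n_perm):
            xp = rng.permutation(x)
            pred = pred0 - contrib + c * (xp - model.gene_mean[j]) / model.gene_scale[j]
            deltas[t] = np.mean(np.abs(pred - y)) - base_mae
        out[g] = float(deltas.mean())
    return out


def feature_stability(
    pb: PseudobulkMatrix,
    n_resamples: int = 20,
    fraction: float = 0.8,
    seed: int = 0,
    **train_kwargs,
) -> pd.Series:
    """Selection frequency of each gene across subsample refits.

    Groups are resampled without replacement at the given fraction; the
    clock is refit on each subsample at the regularization strength
    selected once on the full data, and the frequency with which each
    gene receives a nonzero coefficient is returned.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    base = train_clock(pb, **train_kwargs)
    counts = pd.Series(0.0, index=pd.Index(base.genes, name="gene"))
    n_take = max(2, int(round(fraction * pb.n_groups)))
    rng = np.random.default_rng(seed)
    kwargs = dict(train_kwargs)
    kwargs["lambda_policy"] = base.lambda_
    for _ in range(n_resamples):
        idx = rng.choice(pb.n_groups, size=n_take, replace=False)
        sub = pb.subset_groups(np.sort(idx))
        if sub.groups["age_pcw"].nunique() < 2:
            raise ValueError("degenerate subsample with a single age")
        m = train_clock(sub, **kwargs)
        counts[np.asarray(m.coef_std) != 0] += 1.0
    return counts / n_resamples


def age_correlated_genes(pb: PseudobulkMatrix, min_groups: int = 3) -> dict[str, pd.DataFrame]:
    """Per-study Pearson age correlation for every gene, with BH FDR.

    Returns, per study, a table (gene, r, p, q, n) sorted by q.  Genes
    constant within a study get NA and are excluded from that study's
    FDR correction.
    """
    out: dict[str, pd.DataFrame] = {}
    for study, sub_idx in pb.groups.groupby("study_id").indices.items():
        sub = pb.values[:, sub_idx]
        y = pb.groups["age_pcw"].to_numpy(dtype=float)[sub_idx]
        n = len(y)
        if n < min_groups:
            raise ValueError(f"study {study}: fewer than {min_groups} groups")
        yc = y - y.mean()
        xc = sub - sub.mean(axis=1, keepdims=True)
        sx = np.sqrt((xc**2).sum(axis=1))
        sy = np.sqrt((yc**2).sum())
        constant = sx == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ yc) / (sx * sy)
        r = np.clip(r, -1.0, 1.0)
        r[constant] = np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.isclose(np.abs(r), 1.0)] = 0.0
        q = np.full_like(p, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        out[str(study)] = pd.DataFrame(
            {"gene": pb.genes, "r": r, "p": p, "q": q, "n": n}
        )
    return out


@dataclass
class CoexpressionNetwork:
    """Aggregate rank-standardized gene-gene co-expression in [0, 1]."""

    matrix: np.ndarray
    genes: list[str]
    n_datasets: int
    support: np.ndarray | None = None  # per-pair count of contributing studies

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.genes), len(self.genes)):
            raise ValueError("matrix must be square over genes")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        self.matrix = m

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.genes, columns=self.genes).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CoexpressionNetwork":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(matrix=df.to_numpy(), genes=list(df.columns), n_datasets=0)


def _rank_standardize(corr: np.ndarray) -> np.ndarray:
    """Rank off-diagonal entries (average ties) into (0, 1]; diagonal = 1.

    NaN entries (constant genes) stay NaN and do not consume ranks.
    """
    n = corr.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = corr[iu]
    out = np.full_like(vals, np.nan)
    ok = ~np.isnan(vals)
    if ok.any():
        out[ok] = rankdata(vals[ok], method="average") / ok.sum()
    std = np.full((n, n), np.nan)
    std[iu] = out
    std.T[iu] = out
    np.fill_diagonal(std, 1.0)
    return std


def aggregate_coexpression(pb: PseudobulkMatrix, genes: list[str] | None = None) -> CoexpressionNetwork:
    """Average rank-standardized Spearman co-expression across studies.

    Per study: Spearman correlation between genes over that study's
    pseudobulk groups, rank-standardized into (0, 1].  Matrices are then
    averaged across studies; pairs involving a gene constant within a
    study are excluded from that study's contribution (support counts
    are tracked per pair).
    """
    if genes is not None:
        pb = pb.subset_genes(genes)
    if len(pb.genes) < 2:
        raise ValueError("need >= 2 genes")
    n = len(pb.genes)
    total = np.zeros((n, n))
    support = np.zeros((n, n), dtype=int)
    n_studies = 0
    for study, idx in pb.groups.groupby("study_id").indices.items():
        if len(idx) < 2:
            raise ValueError(f"study {study}: fewer than 2 groups")
        sub = pb.values[:, idx]
        ranks = rankdata(sub, axis=1, method="average")
        sd = ranks.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(ranks)
        corr[sd == 0, :] = np.nan
        corr[:, sd == 0] = np.nan
        std = _rank_standardize(corr)
        ok = ~np.isnan(std)
        total[ok] += std[ok]
        support += ok.astype(int)
        n_studies += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = total / support
    np.fill_diagonal(avg, 1.0)
    return CoexpressionNetwork(matrix=avg, genes=list(pb.genes), n_datasets=n_studies, support=support)


@dataclass
class ModuleSet:
    """Hard module assignment of clustered genes."""

    assignments: pd.Series  # gene -> module id (1-based)
    height: float
    linkage: str = "complete"
    sign_stratum: str | None = None

    @property
    def n_modules(self) -> int:
        return int(self.assignments.nunique())

    def members(self, module_id: int) -> list[str]:
        return list(self.assignments.index[self.assignments == module_id])

    def as_dict(self) -> dict[int, list[str]]:
        return {int(m): self.members(int(m)) for m in sorted(self.assignments.unique())}


def detect_modules(
    network: CoexpressionNetwork,
    height: float = 2.0,
    sign_stratum: str | None = None,
    method: str = "complete",
) -> ModuleSet:
    """Cut a hierarchical clustering of network rows at a height.

    Distance is Euclidean between rows of the aggregate network;
    agglomeration is complete-linkage by default.  Singleton modules are
    allowed.
    """
    if len(network.genes) < 2:
        raise ValueError("need >= 2 genes to cluster")
    if height <= 0:
        raise ValueError("height must be > 0")
    mat = np.nan_to_num(network.matrix, nan=0.5)
    d = pdist(mat, metric="euclidean")
    Z = linkage(d, method=method)
    labels = fcluster(Z, t=height, criterion="distance")
    return ModuleSet(
        assignments=pd.Series(labels, index=pd.Index(network.genes, name="gene")),
        height=height,
        linkage=method,
        sign_stratum=sign_stratum,
    )


def module_set_enrichment(
    modules: ModuleSet | dict[int | str, list[str]],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    test: str = "hypergeometric",
    set_size_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Enrichment of gene sets in modules with BH correction.

    ``test`` is ``"hypergeometric"`` (upper tail) or ``"fisher"``
    (two-sided).  ``set_size_range`` filters gene sets by their size
    within the universe (e.g. (10, 200) for annotation scans).  BH is
    applied across all (module, set) pairs of the call.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    if test not in ("hypergeometric", "fisher"):
        raise ValueError(f"unknown test {test!r}")
    uni = set(universe)
    module_genes = modules.as_dict() if isinstance(modules, ModuleSet) else modules
    rows = []
    for set_id, set_members in gene_sets.items():
        K_set = set(set_members) & uni
        if set_size_range is not None and not (set_size_range[0] <= len(K_set) <= set_size_range[1]):
            continue
        for mod_id, members in module_genes.items():
            M_set = set(members) & uni
            k = len(M_set & K_set)
            m, K, N = len(M_set), len(K_set), len(uni)
            if k > min(m, K):
                raise ValueError("overlap exceeds set sizes")
            table = np.array([[k, m - k], [K - k, N - m - K + k]])
            if test == "hypergeometric":
                p = float(stats.hypergeom.sf(k - 1, N, K, m))
                odds = np.nan
            else:
                odds, p = stats.fisher_exact(table, alternative="two-sided")
            expected = m * K / N
            rows.append(
                {
                    "module": mod_id,
                    "gene_set": set_id,
                    "overlap": k,
                    "module_size": m,
                    "set_size": K,
                    "fold": k / expected if expected > 0 else np.nan,
                    "odds_ratio": odds,
                    "p": p,
                }
            )
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = multipletests(result["p"].to_numpy(), method="fdr_bh")[1]
    return result


def neighbor_voting_auroc(
    network: CoexpressionNetwork,
    module: list[str],
    n_folds: int = 3,
    n_repeats: int = 1,
    seed: int = 0,
    degree_normalize: bool = True,
) -> float:
    """Cross-validated neighbor-voting module-coherence AUROC.

    Per fold, part of the module is hidden; every non-training gene is
    scored by the sum of its network weights to the retained members,
    normalized by its node degree, and the AUROC of hidden members versus
    non-members is computed from midranks.  Folds and repeats are
    averaged.
    """
    gene_index = {g: i for i, g in enumerate(network.genes)}
    missing = [g for g in module if g not in gene_index]
    if missing:
        raise ValueError(f"module genes absent from network: {missing[:3]}")
    module_idx = np.array([gene_index[g] for g in module])
    if len(module_idx) < n_folds:
        raise ValueError("module smaller than n_folds")
    if len(module_idx) >= len(network.genes):
        raise ValueError("module covers the whole network")
    mat = np.nan_to_num(network.matrix, nan=0.0)
    degree = mat.sum(axis=1)
    rng = np.random.default_rng(seed)
    in_module = np.zeros(len(network.genes), dtype=bool)
    in_module[module_idx] = True

    aurocs = []
    for _ in range(n_repeats):
        order = rng.permutation(module_idx)
        for fold in np.array_split(order, n_folds):
            train = np.setdiff1d(module_idx, fold)
            candidates = np.setdiff1d(np.arange(len(network.genes)), train)
            score = mat[np.ix_(candidates, train)].sum(axis=1)
            if degree_normalize:
                with np.errstate(invalid="ignore", divide="ignore"):
                    score = np.where(degree[candidates] > 0, score / degree[candidates], 0.0)
            labels = in_module[candidates]
            aurocs.append(_auroc(score, labels))
    return float(np.mean(aurocs))


def gene_sign_discriminability(
    age_corr: dict[str, pd.DataFrame],
    positive_genes: list[str],
    negative_genes: list[str],
    mode: str = "signed",
) -> pd.Series:
    """Per-study AUROC separating gene classes by age correlation.

    ``mode="signed"``: AUROC of the signed correlation coefficient for
    positive-program versus negative-program genes (1.0 when all
    positives exceed all negatives).  ``mode="abs"``: AUROC of |r| for
    model genes (positive + negative) versus the genome background —
    the negative control that asks whether model genes are simply the
    most age-correlated genes.
    """
    if mode not in ("signed", "abs"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(positive_genes) == 0 or (mode == "signed" and len(negative_genes) == 0):
        raise ValueError("gene classes must be non-empty")
    out = {}
    for study, df in age_corr.items():
        table = df.dropna(subset=["r"]).set_index("gene")
        if mode == "signed":
            genes = [g for g in positive_genes + negative_genes if g in table.index]
            labels = np.array([g in set(positive_genes) for g in genes])
            scores = table.loc[genes, "r"].to_numpy()
        else:
            model_genes = set(positive_genes) | set(negative_genes)
            scores = np.abs(table["r"].to_numpy())
            labels = np.array([g in model_genes for g in table.index])
        out[study] = _auroc(scores, labels)
    return pd.Series(out, name=f"auroc_{mode}")
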