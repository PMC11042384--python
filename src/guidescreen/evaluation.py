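"""Leakage-free evaluation of guide-effect models.

Guides sharing a chromosome or a DHS are never split across folds, so no
information about a held-out region can leak through neighbouring guides.
Model families are compared by paired t-tests across fold-level metrics
with Benjamini-Hochberg adjustment. Within-DHS prioritization asks whether
the guide ranked first by predicted probability really shows stronger
experimental effects than its DHS neighbours, and a 2x2 association links
a guide's impact on cell fitness to its impact on nearby gene expression.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .labels import SIGNIFICANT


# ---------------------------------------------------------------------------
# Grouped folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """guide_id -> fold index (1..k); no grouping key straddles two folds."""

    folds: pd.Series  # index guide_id, values 1..k
    grouping_key: str
    k: int

    def fold_ids(self, fold: int) -> pd.Index:
        return self.folds.index[self.folds == fold]

    def to_tsv(self, path) -> None:
        self.folds.to_csv(path, sep="\t", header=True)

    @classmethod
    def from_tsv(cls, path, grouping_key: str = "unknown") -> "FoldAssignment":
        folds = pd.read_csv(path, sep="\t", index_col="guide_id")["fold"]
        return cls(folds=folds, grouping_key=grouping_key, k=int(folds.max()))


def make_grouped_folds(records: pd.DataFrame, key: str, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Assign whole groups (chromosomes, DHSs, regions) to k folds.

    Groups are shuffled with the seed, then assigned largest-first to the
    currently smallest fold (by guide count), which keeps fold sizes
    approximately balanced while guaranteeing zero group leakage.
    """
    if key not in records.columns:
        raise ValueError(f"grouping key {key!r} not in records")
    if records[key].isna().any():
        raise ValueError(f"grouping key {key!r} has missing values")
    groups = records.groupby(key, sort=True).size()
    if len(groups) < k:
        raise ValueError(f"only {len(groups)} groups for {k} folds")
    rng = np.random.default_rng(seed)
    names = groups.index.to_numpy()
    rng.shuffle(names)
    sizes = groups.loc[names].to_numpy()
    order = np.argsort(-sizes, kind="stable")  # largest first, shuffled ties
    fold_load = np.zeros(k, dtype=int)
    group_fold = {}
    for idx in order:
        target = int(np.argmin(fold_load))
        group_fold[names[idx]] = target + 1
        fold_load[target] += sizes[idx]
    folds = records[key].map(group_fold)
    folds.index = pd.Index(records["guide_id"].astype(str), name="guide_id")
    return FoldAssignment(folds=folds.rename("fold"), grouping_key=key, k=k)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney formulation, midrank ties)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def compare_models(fold_metrics: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise paired t-tests across fold-level metrics, BH-adjusted.

    ``fold_metrics``: rows = folds, columns = models, identical folds for
    every model. Identical metric vectors give t = 0, p = 1; a constant
    nonzero difference (zero variance) is degenerate and reported as p = 0
    with a warning.
    """
    models = list(fold_metrics.columns)
    if fold_metrics.isna().any().any():
        raise ValueError("fold metrics contain missing values (unequal fold counts?)")
    rows = []
    for a, b in itertools.combinations(models, 2):
        diff = fold_metrics[a].to_numpy() - fold_metrics[b].to_numpy()
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        elif np.isclose(diff.std(ddof=1), 0):
            warnings.warn(f"zero-variance nonzero difference for {a} vs {b}; p floored at 0",
                          stacklevel=2)
            t, p = np.sign(diff.mean()) * np.inf, 0.0
        else:
            t, p = stats.ttest_rel(fold_metrics[a], fold_metrics[b])
        rows.append({"model_a": a, "model_b": b, "mean_diff": float(np.mean(diff)),
                     "t_statistic": float(t), "p_value": float(p)})
    table = pd.DataFrame(rows)
    table["adj_p"] = bh_adjust(table["p_value"])
    table["significant"] = table["adj_p"] < alpha
    return table


# ---------------------------------------------------------------------------
# Within-DHS prioritization
# ---------------------------------------------------------------------------

def rank_within_dhs(
    predictions: pd.DataFrame,
    outcomes: pd.DataFrame,
    min_sig: int = 3,
    k: int = 1,
    sig_thresh: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Top-k guides per DHS by predicted probability vs the remainder.

    Only DHSs with at least ``min_sig`` significant guides are considered
    (these are the regions where guide choice matters). Within each DHS,
    guides are ranked by predicted probability, ties broken by larger
    |log2FC| then guide_id. DHSs with fewer than ``k + 1`` guides have no
    remainder and are excluded from the comparison with a warning.

    Returns the ranked table (with ``is_top`` flag) and a dict of
    enrichment statistics: proportion of adj_p < ``sig_thresh`` in each
    group, Wilcoxon rank-sum p-values on adj_p and |log2FC|, and third
    quartiles of |log2FC|.
    """
    df = predictions.merge(outcomes, on="guide_id", how="inner")
    if "dhs_id" not in df.columns:
        raise ValueError("outcomes must carry dhs_id")
    n_sig = df[df["label"] == SIGNIFICANT].groupby("dhs_id").size()
    keep = n_sig[n_sig >= min_sig].index
    df = df[df["dhs_id"].isin(keep)].copy()
    if df.empty:
        raise ValueError(f"no DHS has >= {min_sig} significant guides")

    small = df.groupby("dhs_id").size()
    too_small = small[small < k + 1].index
    if len(too_small):
        warnings.warn(f"{len(too_small)} DHSs have <= {k} guides; excluded from comparison",
                      stacklevel=2)
        df = df[~df["dhs_id"].isin(too_small)]

    df["_abs_lfc"] = df["log2FC"].abs()
    df = df.sort_values(["dhs_id", "score", "_abs_lfc", "guide_id"],
                        ascending=[True, False, False, True], kind="mergesort")
    df["rank"] = df.groupby("dhs_id").cumcount() + 1
    df["is_top"] = df["rank"] <= k

    top = df[df["is_top"]]
    rest = df[~df["is_top"]]
    stats_out = {
        "n_dhs": int(df["dhs_id"].nunique()),
        "n_top": int(len(top)),
        "n_rest": int(len(rest)),
        "top_prop_sig": float((top["adj_p"] < sig_thresh).mean()),
        "rest_prop_sig": float((rest["adj_p"] < sig_thresh).mean()),
        "top_q3_abs_log2fc": float(top["_abs_lfc"].quantile(0.75)),
        "rest_q3_abs_log2fc": float(rest["_abs_lfc"].quantile(0.75)),
        "wilcoxon_p_adj_p": _ranksum_p(top["adj_p"], rest["adj_p"], alternative="less"),
        "wilcoxon_p_abs_log2fc": _ranksum_p(top["_abs_lfc"], rest["_abs_lfc"], alternative="greater"),
    }
    return df.drop(columns="_abs_lfc"), stats_out


def _ranksum_p(a, b, alternative: str) -> float:
    """Wilcoxon rank-sum with midranks: exact for small samples, normal
    approximation otherwise (scipy's automatic policy)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    method = "exact" if max(len(a), len(b)) <= 50 else "asymptotic"
    try:
        return float(stats.mannwhitneyu(a, b, alternative=alternative, method=method).pvalue)
    except ValueError:  # exact method refuses ties; fall back
        return float(stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic").pvalue)


# ---------------------------------------------------------------------------
# Fitness / expression association
# ---------------------------------------------------------------------------

def fitness_expression_association(
    fitness: pd.DataFrame,
    expression_pairs: pd.DataFrame,
    expr_thresh: float = 0.2,
    level: str = "pair",
    yates: bool = False,
    gene_count_cut: int = 3,
) -> dict:
    """Association between a guide's fitness impact and its expression impact.

    ``fitness`` needs guide_id + label; ``expression_pairs`` needs
    guide_id, gene_id, adj_p. At ``level='pair'`` the 2x2 table counts
    gRNA-gene pairs (fitness-significant vs not x expression adj_p <
    ``expr_thresh`` vs not); at ``level='guide'`` it counts guides (any
    significant gene vs none). The odds ratio is ad/bc with a
    Haldane-Anscombe 0.5 correction (flagged) when a margin is zero;
    chi-square is computed without Yates continuity correction unless
    requested. A secondary 2x2 tests enrichment of guides influencing
    more than ``gene_count_cut`` genes.
    """
    fit = fitness[["guide_id", "label"]].drop_duplicates("guide_id")
    pairs = expression_pairs.merge(fit, on="guide_id", how="inner")
    if pairs.empty:
        raise ValueError("no guides shared between the fitness and expression screens")
    pairs["fit_sig"] = pairs["label"] == SIGNIFICANT
    pairs["expr_sig"] = pairs["adj_p"] < expr_thresh

    if level == "pair":
        unit = pairs
    elif level == "guide":
        unit = pairs.groupby("guide_id").agg(fit_sig=("fit_sig", "first"),
                                             expr_sig=("expr_sig", "any")).reset_index()
    else:
        raise ValueError("level must be 'pair' or 'guide'")

    table = _two_by_two(unit["fit_sig"], unit["expr_sig"])
    result = _table_stats(table, yates)
    result["level"] = level

    per_guide = pairs.groupby("guide_id").agg(fit_sig=("fit_sig", "first"),
                                              n_sig_genes=("expr_sig", "sum")).reset_index()
    multi = _two_by_two(per_guide["fit_sig"], per_guide["n_sig_genes"] > gene_count_cut)
    result["multi_gene"] = _table_stats(multi, yates)
    result["per_guide_sig_gene_counts"] = per_guide
    return result


def _two_by_two(rows: pd.Series, cols: pd.Series) -> np.ndarray:
    return np.array([
        [int((rows & cols).sum()), int((rows & ~cols).sum())],
        [int((~rows & cols).sum()), int((~rows & ~cols).sum())],
    ], dtype=float)


def _table_stats(table: np.ndarray, yates: bool) -> dict:
    a, b = table[0]
    c, d = table[1]
    corrected = False
    if min(a, b, c, d) == 0:
        # Haldane-Anscombe correction keeps the OR (and, for an empty
        # margin, the chi-square) defined; flagged in the output
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    odds_ratio = (a * d) / (b * c)
    chi_table = table if table.sum(0).min() > 0 and table.sum(1).min() > 0 else np.array([[a, b], [c, d]])
    chi2, p, _, _ = stats.chi2_contingency(chi_table, correction=yates)
    return {"table": table, "odds_ratio": float(odds_ratio),
            "chi2": float(chi2), "p_value": float(p),
            "haldane_corrected": corrected, "yates": yates}


# ---------------------------------------------------------------------------
# Cross-context transfer
# ---------------------------------------------------------------------------

def cross_cell_evaluate(
    datasets: dict,
    fit_fn,
    predict_fn,
    key: str = "dhs_id",
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Train-on-one, test-on-another transfer matrix across cell contexts.

    ``datasets`` maps context name -> dict with ``records`` (guide table
    carrying the grouping key), ``X`` (feature object passed through to the
    fit/predict callables, indexable by integer position list), and ``y``
    (binary labels). ``fit_fn(X, y, seed) -> model`` and
    ``predict_fn(model, X) -> scores``. Every (train, test) pair is scored
    on the test context's held-out region-grouped folds and averaged: on
    the diagonal the model is refit per fold on the remaining folds (true
    cross-validation); off the diagonal the model is fit once on the full
    training context.

    Feature manifests must agree across contexts.
    """
    names = list(datasets)
    manifests = {n: tuple(_feature_manifest(d["X"])) for n, d in datasets.items()}
    first = manifests[names[0]]
    for n, m in manifests.items():
        if m != first:
            raise ValueError(f"feature manifest of context {n!r} differs from {names[0]!r}")

    folds = {n: make_grouped_folds(d["records"], key=key, k=k, seed=seed) for n, d in datasets.items()}
    full_models = {n: fit_fn(d["X"], d["y"], seed) for n, d in datasets.items()}

    matrix = pd.DataFrame(index=names, columns=names, dtype=float)
    for test in names:
        d = datasets[test]
        assign = folds[test].folds.to_numpy()
        y = np.asarray(d["y"])
        for train in names:
            per_fold = []
            for fold in range(1, k + 1):
                te = np.flatnonzero(assign == fold)
                if len(np.unique(y[te])) < 2:
                    continue
                if train == test:
                    tr = np.flatnonzero(assign != fold)
                    model = fit_fn(_take(d["X"], tr), y[tr], seed)
                else:
                    model = full_models[train]
                scores = predict_fn(model, _take(d["X"], te))
                per_fold.append(auc(scores, y[te]))
            matrix.loc[train, test] = float(np.mean(per_fold))
    return matrix


def _feature_manifest(X):
    if isinstance(X, pd.DataFrame):
        return list(X.columns)
    if isinstance(X, tuple):  # (one_hot, annotations) pair for the CNN
        ann = X[1]
        return ["__onehot__"] + (list(ann.columns) if isinstance(ann, pd.DataFrame)
                                 else [f"ann_{i}" for i in range(0 if ann is None else ann.shape[1])])
    return [f"f{i}" for i in range(X.shape[1])]


def _take(X, idx):
    if isinstance(X, pd.DataFrame):
        return X.iloc[idx]
    if isinstance(X, tuple):
        return tuple(None if part is None else _take(part, idx) for part in X)
    return X[idx]
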