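"""Evaluation protocol: AUC, hierarchical metrics, CV, rank-sum, pruning.

Hierarchical precision/recall compare ancestor-closed predicted and true
term sets per sample (root excluded), the ancestor-based variant of the
hierarchical P/R family:

    HP = |P & T| / |P|,  HR = |P & T| / |T|,  HF = harmonic mean,

macro-averaged over samples, with the conventions HP=1 when both sets are
empty and HP=0 when only the prediction is empty (symmetrically for HR).

The cross-validation driver reproduces the comparison protocol: per fold,
train a margin scorer per term on the remaining genes, estimate channel
variances from training positives, then score held-out genes with the flat
baseline, TPR-DAG (Platt-calibrated probabilities) and factor-graph
inference, accumulating per-term AUC and hierarchical metrics.  Methods are
compared with the two-sided Wilcoxon rank-sum test (default alpha 0.01).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.metrics import roc_auc_score

from . import flat as flat_mod
from .channel import ETA_FLOOR, estimate_variance
from .errors import UndefinedMetricError
from .factor_graph import check_consistency, repair_matrix
from .inference import DEFAULT_I_MAX, DEFAULT_XI, fgga_annotate
from .ontology import GoDag, is_ancestor_closed, select_subdag
from .tpr_dag import tpr_dag_predict

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
DEFAULT_LEAF_CUT = 0.95


# ---------------------------------------------------------------------------
# Per-term AUC
# ---------------------------------------------------------------------------

def term_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative).

    Ties count one half; undefined when only one class is present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("AUC undefined with a single class")
    return float(roc_auc_score(y, s))


# ---------------------------------------------------------------------------
# Hierarchical precision / recall / F
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HierMetrics:
    """Macro-averaged hierarchical precision, recall and F-score."""

    HP: float
    HR: float
    HF: float


def hierarchical_prf(
    dag: GoDag, predicted: pd.DataFrame, truth: pd.DataFrame
) -> HierMetrics:
    """Ancestor-based hierarchical P/R/F over closed label sets.

    Both frames must be ancestor-closed (apply
    :func:`fgga.factor_graph.repair_labels` first if needed); the root
    column is excluded before set comparison.  HF is the per-sample
    harmonic mean, averaged afterwards.
    """
    for name, frame in (("predicted", predicted), ("truth", truth)):
        if not is_ancestor_closed(dag, frame):
            raise ValueError(
                f"{name} labels are not ancestor-closed; apply repair_labels first"
            )
    terms = [t for t in dag.term_ids if t != dag.root]
    P = predicted[terms].to_numpy(dtype=bool)
    T = truth[terms].to_numpy(dtype=bool)
    if P.shape != T.shape:
        raise ValueError("predicted and truth frames must align")
    inter = (P & T).sum(axis=1).astype(float)
    psz = P.sum(axis=1).astype(float)
    tsz = T.sum(axis=1).astype(float)
    hp = np.where(psz > 0, inter / np.maximum(psz, 1), (tsz == 0).astype(float))
    hr = np.where(tsz > 0, inter / np.maximum(tsz, 1), (psz == 0).astype(float))
    denom = hp + hr
    hf = np.where(denom > 0, 2 * hp * hr / np.maximum(denom, 1e-300), 0.0)
    return HierMetrics(HP=float(hp.mean()), HR=float(hr.mean()), HF=float(hf.mean()))


# ---------------------------------------------------------------------------
# Rank-sum comparison
# ---------------------------------------------------------------------------

def ranksum_compare(
    metric_a, metric_b, alpha: float = DEFAULT_ALPHA
) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum test between paired method metrics.

    Uses the exact null distribution when the combined sample is small
    (<= 20) and untied, the tie-corrected normal approximation otherwise.
    Returns (statistic, p-value, verdict) with verdict ``'a'``, ``'b'`` or
    ``'tie'``; a winner is declared only when p < alpha.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    stat, p = mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = min(float(p), 1.0)
    if p >= alpha:
        return float(stat), p, "tie"
    # direction: mean rank of a above b means a wins
    ranks = rankdata(pooled)
    winner = "a" if ranks[: a.size].mean() > ranks[a.size :].mean() else "b"
    return float(stat), p, winner


# ---------------------------------------------------------------------------
# Leaf-confidence pruning of predicted graphs
# ---------------------------------------------------------------------------

@dataclass
class PrunedPrediction:
    """Ancestor-closed predicted subgraph after leaf-confidence pruning."""

    kept: tuple[str, ...]
    leaves: dict[str, float]  # leaf term -> marginal
    top: list[tuple[str, float]]  # top-k leaves by marginal, descending


def prune_predicted_graph(
    dag: GoDag,
    marginals: pd.Series,
    leaf_cut: float = DEFAULT_LEAF_CUT,
    top_k: int = 5,
) -> PrunedPrediction:
    """Trim low-confidence leaves from the MAP-positive subgraph.

    Starting from the repaired positive set (marginal > 0.5), leaf terms of
    the current subgraph with marginal below *leaf_cut* are removed
    iteratively — removal can expose a parent as a new leaf, which is then
    tested too.  The kept set stays ancestor-closed because only leaves are
    ever removed.
    """
    if not 0.0 <= leaf_cut <= 1.0:
        raise ValueError(f"leaf_cut must be in [0, 1], got {leaf_cut}")
    from .factor_graph import repair_labels

    labels = repair_labels(dag, {t: int(marginals[t] > 0.5) for t in dag.term_ids})
    kept = {t for t, v in labels.items() if v == 1}
    while True:
        leaves = {
            t for t in kept
            if t != dag.root and not any(c in kept for c in dag.children(t))
        }
        drop = {t for t in leaves if marginals[t] < leaf_cut}
        if not drop:
            break
        kept -= drop
    leaves = {
        t: float(marginals[t])
        for t in kept
        if t != dag.root and not any(c in kept for c in dag.children(t))
    }
    top = sorted(leaves.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return PrunedPrediction(kept=tuple(sorted(kept)), leaves=leaves, top=top)


# ---------------------------------------------------------------------------
# Cross-validation protocol
# ---------------------------------------------------------------------------

@dataclass
class CrossValResult:
    """Per-fold scores and metrics for flat / TPR-DAG / FGGA."""

    folds: pd.Series  # gene -> fold id
    auc: dict[str, pd.DataFrame]  # method -> terms x folds AUC (NaN where undefined)
    hier: pd.DataFrame  # rows (method, fold), columns HP/HR/HF
    excluded: list[str] = field(default_factory=list)

    def mean_auc(self) -> pd.DataFrame:
        """Per-term AUC averaged over folds, one column per method."""
        return pd.DataFrame(
            {m: df.mean(axis=1, skipna=True) for m, df in self.auc.items()}
        )

    def mean_hier(self) -> pd.DataFrame:
        return self.hier.groupby(level="method").mean()


def stratified_folds(matrix: pd.DataFrame, k: int, seed: int) -> pd.Series:
    """Partition genes into k folds, balancing positives of rare terms first.

    Terms are visited by increasing positive count; each term's unassigned
    positive genes are dealt round-robin over the folds (shuffled under
    *seed*), then remaining genes are dealt the same way.  Per-term positive
    counts per fold end within +/-1 of the stratifiable ideal.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    assigned: dict[str, int] = {}
    fold_sizes = np.zeros(k, dtype=int)

    def deal(genes, term_counts):
        order = list(genes)
        rng.shuffle(order)
        for g in order:
            # least-loaded fold for this term, global size breaking ties
            f = min(range(k), key=lambda i: (term_counts[i], fold_sizes[i], i))
            assigned[g] = f
            term_counts[f] += 1
            fold_sizes[f] += 1

    counts = matrix.sum(axis=0).sort_values(kind="stable")
    for term in counts.index:
        pos = matrix.index[matrix[term] == 1]
        term_counts = np.zeros(k, dtype=int)
        for g in pos:
            if g in assigned:
                term_counts[assigned[g]] += 1
        deal([g for g in pos if g not in assigned], term_counts)
    deal([g for g in matrix.index if g not in assigned], np.zeros(k, dtype=int))
    return pd.Series({g: assigned[g] for g in matrix.index}, name="fold")


def cross_validate(
    matrix: pd.DataFrame,
    features: pd.DataFrame,
    dag: GoDag,
    k: int = 5,
    seed: int = 0,
    scorer=None,
    max_neg_ratio: float = flat_mod.DEFAULT_MAX_NEG_RATIO,
    xi: float = DEFAULT_XI,
    i_max: int = DEFAULT_I_MAX,
    damping: float = 0.0,
) -> CrossValResult:
    """k-fold protocol comparing flat, TPR-DAG and factor-graph inference.

    Per fold: per-term scorers are trained on the training genes' inclusive
    datasets; channel variances come from the training positives' margins;
    sigmoid calibrations feed TPR-DAG.  Terms that cannot be trained in a
    fold (too few positives or no negatives) keep an uninformative score
    (margin 0 / probability 0.5) and are excluded from that fold's AUC, with
    a logged warning.  The root never has a classifier.
    """
    scorer = scorer if scorer is not None else flat_mod.default_scorer()
    folds = stratified_folds(matrix, k=k, seed=seed)
    methods = ("flat", "tpr_dag", "fgga")
    auc: dict[str, pd.DataFrame] = {
        m: pd.DataFrame(np.nan, index=list(dag.term_ids), columns=range(k))
        for m in methods
    }
    hier_rows = []
    excluded: list[str] = []

    for f in range(k):
        test_genes = folds.index[folds == f]
        train_genes = folds.index[folds != f]
        train_m = matrix.loc[train_genes]

        datasets = {}
        for term in dag.term_ids:
            if term == dag.root:
                continue
            try:
                datasets[term] = flat_mod.build_binary_dataset(
                    term, train_m, dag, max_neg_ratio=max_neg_ratio,
                    seed=seed * 1000 + f,
                )
                if len(datasets[term].positives) < 2:
                    raise flat_mod.InsufficientDataError(
                        f"term {term!r}: <2 training positives"
                    )
            except flat_mod.InsufficientDataError as exc:
                del_msg = f"fold {f}: excluded {term}: {exc}"
                excluded.append(del_msg)
                logger.warning(del_msg)
                datasets.pop(term, None)

        sm = flat_mod.score_terms(scorer, datasets, features)
        trained = list(sm.terms)

        # Channel variances and Platt calibrations from training-fold data.
        eta = pd.Series(1.0, index=list(dag.term_ids))
        probs_cols = {}
        for term in dag.term_ids:
            if term not in trained:
                probs_cols[term] = pd.Series(0.5, index=test_genes)
                continue
            ds = datasets[term]
            train_scores = sm.scores.loc[list(ds.positives), term]
            eta[term] = estimate_variance(train_scores, term=term)
            calib_genes = list(ds.positives) + list(ds.negatives)
            calib = flat_mod.fit_sigmoid(
                sm.scores.loc[calib_genes, term],
                [1] * len(ds.positives) + [0] * len(ds.negatives),
            )
            probs_cols[term] = pd.Series(
                calib.predict(sm.scores.loc[test_genes, term]), index=test_genes
            )

        flat_scores = pd.DataFrame(0.0, index=test_genes, columns=list(dag.term_ids))
        flat_scores[trained] = sm.scores.loc[test_genes, trained]
        probs = pd.DataFrame(probs_cols)[list(dag.term_ids)]

        truth = matrix.loc[test_genes, list(dag.term_ids)]
        flat_raw = (flat_scores > 0).astype("int8")
        flat_raw[dag.root] = 1  # the root has no classifier; annotated genes hit it
        flat_labels = repair_matrix(dag, flat_raw)
        tpr_probs, tpr_labels = tpr_dag_predict(dag, probs)
        result = fgga_annotate(dag, flat_scores, eta, xi=xi, i_max=i_max,
                               damping=damping)

        per_method_scores = {
            "flat": flat_scores,
            "tpr_dag": tpr_probs,
            "fgga": result.marginals,
        }
        per_method_labels = {
            "flat": flat_labels,
            "tpr_dag": tpr_labels,
            "fgga": result.map_repaired,
        }
        for m in methods:
            for term in trained:
                y = truth[term]
                if y.nunique() < 2:
                    continue
                auc[m].loc[term, f] = term_auc(per_method_scores[m][term], y)
            hm = hierarchical_prf(dag, per_method_labels[m], truth)
            hier_rows.append((m, f, hm.HP, hm.HR, hm.HF))

    hier = pd.DataFrame(
        hier_rows, columns=["method", "fold", "HP", "HR", "HF"]
    ).set_index(["method", "fold"])
    return CrossValResult(folds=folds, auc=auc, hier=hier, excluded=excluded)
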