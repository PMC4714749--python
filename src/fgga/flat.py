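"""Per-term flat classification: training sets, margins and calibration.

Each ontology term gets a binary training set under the *inclusive*
negative policy: positives are the genes positive for the term after
ancestor closure; candidate negatives are genes annotated somewhere in the
sub-DAG but not to the term (closure automatically excludes annotators of
its descendants).  Negatives are subsampled to a configurable multiple of
the positives with a fixed seed.

The classifier is a pluggable margin-producing scorer (scikit-learn
estimator protocol: ``fit`` + ``decision_function``); the reference scorer
is a soft-margin linear SVM with complexity constant C=1.  Platt's sigmoid
fitting maps margins to calibrated probabilities for the TPR-DAG baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import clone
from sklearn.svm import LinearSVC

from .channel import ScoreMatrix
from .errors import CalibrationError, InsufficientDataError
from .ontology import GoDag

DEFAULT_MAX_NEG_RATIO = 2.0


@dataclass(frozen=True)
class BinaryTermDataset:
    """Positive/negative gene sets for one term's binary classifier."""

    term: str
    positives: tuple[str, ...]
    negatives: tuple[str, ...]

    def __post_init__(self):
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"genes in both classes: {sorted(overlap)[:5]}")


def build_binary_dataset(
    term: str,
    matrix: pd.DataFrame,
    dag: GoDag,
    max_neg_ratio: float = DEFAULT_MAX_NEG_RATIO,
    seed: int = 0,
) -> BinaryTermDataset:
    """Assemble the inclusive-policy training set for *term*.

    *matrix* must be the ancestor-closed annotation matrix of the sub-DAG.
    Candidate negatives (annotated in the sub-DAG, negative for the term)
    are subsampled to at most ``max_neg_ratio * n_positives``, reproducibly
    under *seed*.
    """
    dag.term(term)
    if max_neg_ratio <= 0:
        raise ValueError(f"max_neg_ratio must be > 0, got {max_neg_ratio}")
    col = matrix[term]
    positives = tuple(sorted(matrix.index[col == 1]))
    if not positives:
        raise InsufficientDataError(f"no positive genes for term {term!r}")
    annotated = matrix.index[(matrix == 1).any(axis=1)]
    candidates = sorted(set(annotated) - set(positives))
    if not candidates:
        raise InsufficientDataError(f"no candidate negatives for term {term!r}")
    cap = int(max_neg_ratio * len(positives))
    if cap < len(candidates):
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(candidates), size=cap, replace=False)
        negatives = tuple(candidates[i] for i in sorted(chosen))
    else:
        negatives = tuple(candidates)
    return BinaryTermDataset(term=term, positives=positives, negatives=negatives)


@dataclass(frozen=True)
class SigmoidCalibration:
    """Platt calibration p(margin m) = 1 / (1 + exp(A*m + B))."""

    A: float
    B: float

    def predict(self, margins) -> np.ndarray:
        m = np.asarray(margins, dtype=float)
        return expit(-(self.A * m + self.B))


def fit_sigmoid(margins: Sequence[float], labels: Sequence[int]) -> SigmoidCalibration:
    """Platt's sigmoid fit of margins to probabilities.

    Minimises the Bernoulli negative log-likelihood with Platt's smoothed
    targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2), which regularises the
    fit away from hard 0/1 probabilities.
    """
    m = np.asarray(margins, dtype=float)
    t = np.asarray(labels, dtype=int)
    if m.shape != t.shape:
        raise ValueError("margins and labels must have equal length")
    n_pos = int(np.sum(t == 1))
    n_neg = int(np.sum(t == 0))
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError(
            f"both classes required, got {n_pos} positives / {n_neg} negatives"
        )
    target = np.where(t == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll_grad(ab):
        a, b = ab
        z = a * m + b
        q = expit(z)  # 1 - p
        # -sum t*log(p) + (1-t)*log(1-p) with p = expit(-z), in softplus form
        nll = float(np.sum(target * z + np.logaddexp(0.0, -z)))
        # d/dz of the per-sample loss:
        dz = target * q - (1.0 - target) * (1.0 - q)
        return nll, np.array([np.sum(dz * m), np.sum(dz)])

    # Initial slope from class prior, as in Platt's pseudocode.
    b0 = math.log((n_neg + 1.0) / (n_pos + 1.0))
    res = minimize(nll_grad, x0=np.array([0.0, b0]), jac=True, method="BFGS")
    a, b = res.x
    return SigmoidCalibration(A=float(a), B=float(b))


def default_scorer() -> LinearSVC:
    """Reference margin scorer: soft-margin linear SVM, C = 1."""
    return LinearSVC(C=1.0)


def score_terms(
    scorer,
    datasets: Mapping[str, BinaryTermDataset] | Sequence[BinaryTermDataset],
    features: pd.DataFrame,
) -> ScoreMatrix:
    """Train one scorer per term and emit margins for every gene.

    *scorer* is a prototype estimator cloned per term (``fit`` on the term's
    training genes, ``decision_function`` on all genes in *features*).
    Genes outside a term's training set receive prediction-only scores.
    """
    if not isinstance(datasets, Mapping):
        datasets = {d.term: d for d in datasets}
    X_all = features.to_numpy(dtype=float)
    cols = {}
    for term in sorted(datasets):
        ds = datasets[term]
        train_genes = list(ds.positives) + list(ds.negatives)
        missing = [g for g in train_genes if g not in features.index]
        if missing:
            raise KeyError(f"term {term!r}: genes missing features {missing[:5]}")
        X = features.loc[train_genes].to_numpy(dtype=float)
        y = np.array([1] * len(ds.positives) + [0] * len(ds.negatives))
        model = clone(scorer)
        try:
            model.fit(X, y)
            cols[term] = model.decision_function(X_all)
        except Exception as exc:
            raise RuntimeError(f"scorer failed for term {term!r}: {exc}") from exc
    scores = pd.DataFrame(cols, index=features.index)
    return ScoreMatrix(scores=scores)


#: Type of scorer factories accepted by the cross-validation driver.
ScorerFactory = Callable[[], object]
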