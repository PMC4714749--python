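"""True Path Rule heuristic for DAG-structured ontologies (TPR-DAG).

The comparison baseline: flat per-term probabilities are leveraged in two
sweeps.  A bottom-up sweep (deepest terms first, by maximum distance to the
root) replaces each term's value with the mean of its own flat value and
the consensus values of its *positive* children (consensus >= threshold,
default 0.5).  A top-down sweep then forces every child not to exceed its
weakest parent, so thresholding the corrected values at any level yields a
TPG-consistent label set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ontology import GoDag

DEFAULT_THRESHOLD = 0.5


@dataclass
class LevelledDag:
    """A DAG with each term's maximum edge distance to the root.

    Along every edge depth(child) > depth(parent), since any root path of
    the parent extends to the child.
    """

    dag: GoDag
    depth: dict[str, int]


def max_depths(dag: GoDag) -> LevelledDag:
    """Longest-path distance from the root, by DP in topological order."""
    depth: dict[str, int] = {}
    for t in dag.topological_order():
        if t == dag.root:
            depth[t] = 0
        else:
            depth[t] = 1 + max(depth[p] for p in dag.parents(t))
    return LevelledDag(dag=dag, depth=depth)


def _as_frame(flat) -> tuple[pd.DataFrame, bool]:
    if isinstance(flat, pd.Series):
        return flat.to_frame().T, True
    return flat, False


def _check_probs(values: np.ndarray) -> None:
    if np.any((values < 0) | (values > 1)):
        raise ValueError("probabilities must lie in [0, 1]")


def bottom_up_consensus(
    ldag: LevelledDag,
    flat: pd.DataFrame | pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
):
    """Average each term's flat value with its positive children's consensus.

    Terms are processed once each, from the deepest level up (ties broken by
    identifier), so a child's consensus is final before any parent reads it.
    Leaves keep their flat values.
    """
    frame, squeeze = _as_frame(flat)
    dag = ldag.dag
    vals = {t: frame[t].to_numpy(dtype=float) for t in dag.term_ids}
    _check_probs(np.stack(list(vals.values())))
    order = sorted(dag.term_ids, key=lambda t: (-ldag.depth[t], t))
    for t in order:
        kids = dag.children(t)
        if not kids:
            continue
        num = vals[t].copy()
        den = np.ones_like(num)
        for c in kids:
            pos = vals[c] >= threshold
            num += np.where(pos, vals[c], 0.0)
            den += pos
        vals[t] = num / den
    out = pd.DataFrame(vals, index=frame.index)[list(frame.columns)]
    return out.iloc[0] if squeeze else out


def top_down_correction(ldag: LevelledDag, consensus: pd.DataFrame | pd.Series):
    """Cap every term at its weakest (minimum) corrected parent value.

    Processed from the root down, so parents are final before children are
    corrected; values never increase.  Thresholding the output at any level
    gives a TPG-consistent label set.
    """
    frame, squeeze = _as_frame(consensus)
    dag = ldag.dag
    vals = {t: frame[t].to_numpy(dtype=float) for t in dag.term_ids}
    _check_probs(np.stack(list(vals.values())))
    order = sorted(dag.term_ids, key=lambda t: (ldag.depth[t], t))
    for t in order:
        if t == dag.root:
            continue
        weakest = np.minimum.reduce([vals[p] for p in dag.parents(t)])
        vals[t] = np.minimum(vals[t], weakest)
    out = pd.DataFrame(vals, index=frame.index)[list(frame.columns)]
    return out.iloc[0] if squeeze else out


def tpr_dag_predict(
    dag: GoDag,
    flat: pd.DataFrame | pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
):
    """Full TPR-DAG pipeline: level, consensus, correction, threshold.

    Returns (final probabilities, binary labels), labels positive where the
    corrected probability is >= *threshold*.
    """
    frame, squeeze = _as_frame(flat)
    missing = set(dag.term_ids) - set(frame.columns)
    if missing:
        raise ValueError(f"flat predictions missing terms {sorted(missing)[:5]}")
    ldag = max_depths(dag)
    consensus = bottom_up_consensus(ldag, frame, threshold=threshold)
    corrected = top_down_correction(ldag, consensus)
    labels = (corrected >= threshold).astype("int8")
    if squeeze:
        return corrected.iloc[0], labels.iloc[0]
    return corrected, labels
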