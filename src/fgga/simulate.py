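"""Synthetic ontologies, consistent annotations and noisy scores.

Everything the pipeline consumes can be generated here so that the full
method is testable without external ontology or annotation data: rooted
random level DAGs, annotation matrices drawn term-by-term under the
"all parents positive" conditional (so generated data always satisfies the
true-path-graph constraint the logical factors encode), and score matrices
obtained by corrupting the +1/-1 annotations with additive Gaussian noise
of per-term variance, matching the channel model used at inference time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channel import ETA_FLOOR, ScoreMatrix
from .factor_graph import labels_to_spin
from .ontology import GoDag, GoTerm

SYNTHETIC_NAMESPACE = "synthetic_function"


@dataclass(frozen=True)
class DagSpec:
    """Shape parameters of a random rooted level DAG."""

    n_terms: int
    n_levels: int
    max_parents: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < 1 or self.n_levels < 1 or self.max_parents < 1:
            raise ValueError("n_terms, n_levels and max_parents must be >= 1")
        if self.n_levels > self.n_terms:
            raise ValueError(
                f"n_levels={self.n_levels} exceeds n_terms={self.n_terms}"
            )
        if self.n_terms > 1 and self.n_levels < 2:
            raise ValueError("n_terms > 1 requires n_levels >= 2")


@dataclass(frozen=True)
class SimSpec:
    """Annotation / score generation parameters.

    theta is the per-edge conditional probability that a term is positive
    given all its parents are positive; eta is the channel noise variance
    (scalar, applied to every term, or a per-term mapping).
    """

    theta: float = 0.8
    eta: float = 0.25
    n_samples: int = 500
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must be in [0, 1], got {self.theta}")
        etas = np.asarray(
            list(self.eta.values()) if isinstance(self.eta, dict) else [self.eta]
        )
        if np.any(etas < ETA_FLOOR):
            raise ValueError(f"eta must be >= {ETA_FLOOR}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def random_godag(spec: DagSpec) -> GoDag:
    """Random rooted DAG with terms assigned to levels.

    The root sits alone at level 0; each remaining level is guaranteed at
    least one term; every non-root term draws 1..max_parents parents
    uniformly from strictly shallower levels.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [_term_id(i + 1) for i in range(spec.n_terms)]
    levels = {ids[0]: 0}
    # one term per non-root level, remainder spread uniformly
    rest = ids[1:]
    for lvl in range(1, spec.n_levels):
        levels[rest[lvl - 1]] = lvl
    for tid in rest[spec.n_levels - 1 :]:
        levels[tid] = int(rng.integers(1, spec.n_levels))
    edges = []
    for tid in rest:
        shallower = [t for t in ids if levels[t] < levels[tid]]
        k = int(rng.integers(1, min(spec.max_parents, len(shallower)) + 1))
        parents = rng.choice(len(shallower), size=k, replace=False)
        edges.extend((tid, shallower[p]) for p in sorted(parents))
    terms = [
        GoTerm(tid, name=f"synthetic term {i + 1}", namespace=SYNTHETIC_NAMESPACE)
        for i, tid in enumerate(ids)
    ]
    return GoDag(terms, edges)


def sample_annotations(dag: GoDag, sim: SimSpec) -> pd.DataFrame:
    """Draw TPG-consistent binary annotations, one row per sample.

    The root is positive in every sample; in topological order each term is
    positive with probability theta when all its parents are positive and
    negative otherwise, so every sample is ancestor-closed by construction.
    """
    rng = np.random.default_rng(sim.seed)
    cols: dict[str, np.ndarray] = {}
    for t in dag.topological_order():
        if t == dag.root:
            cols[t] = np.ones(sim.n_samples, dtype="int8")
            continue
        gate = np.ones(sim.n_samples, dtype=bool)
        for p in dag.parents(t):
            gate &= cols[p] == 1
        draw = rng.random(sim.n_samples) < sim.theta
        cols[t] = (gate & draw).astype("int8")
    index = [f"g{i + 1:05d}" for i in range(sim.n_samples)]
    return pd.DataFrame(cols, index=index)[list(dag.term_ids)]


def corrupt_scores(matrix: pd.DataFrame, sim: SimSpec) -> ScoreMatrix:
    """Emit y = x + N(0, eta) scores from +1/-1 encoded annotations."""
    rng = np.random.default_rng(sim.seed + 1)  # decoupled from label draws
    x = labels_to_spin(matrix.to_numpy(dtype=float))
    if isinstance(sim.eta, dict):
        eta = pd.Series({t: float(sim.eta[t]) for t in matrix.columns})
    else:
        eta = pd.Series(float(sim.eta), index=matrix.columns)
    noise = rng.standard_normal(x.shape) * np.sqrt(eta.to_numpy())[None, :]
    scores = pd.DataFrame(x + noise, index=matrix.index, columns=matrix.columns)
    return ScoreMatrix(scores=scores, variances=eta)


# ---------------------------------------------------------------------------
# Small fixed fixtures
# ---------------------------------------------------------------------------

def diamond_dag() -> GoDag:
    """Four-term diamond: one child with two parents under a single root.

    The child's logical factor spans both parents, the minimal multiple-
    inheritance case whose truth table has 8 rows.
    """
    terms = [
        GoTerm("GO:0000001", "root", SYNTHETIC_NAMESPACE),
        GoTerm("GO:0000002", "left parent", SYNTHETIC_NAMESPACE),
        GoTerm("GO:0000003", "right parent", SYNTHETIC_NAMESPACE),
        GoTerm("GO:0000004", "child", SYNTHETIC_NAMESPACE),
    ]
    edges = [
        ("GO:0000002", "GO:0000001"),
        ("GO:0000003", "GO:0000001"),
        ("GO:0000004", "GO:0000002"),
        ("GO:0000004", "GO:0000003"),
    ]
    return GoDag(terms, edges)


def toy7_dag() -> GoDag:
    """Seven-term, two-branch toy DAG with one diamond and one chain."""
    terms = [GoTerm(_term_id(i), f"toy term {i}", SYNTHETIC_NAMESPACE)
             for i in range(1, 8)]
    edges = [
        (_term_id(2), _term_id(1)),
        (_term_id(3), _term_id(1)),
        (_term_id(4), _term_id(2)),
        (_term_id(4), _term_id(3)),
        (_term_id(5), _term_id(2)),
        (_term_id(6), _term_id(5)),
        (_term_id(7), _term_id(4)),
    ]
    return GoDag(terms, edges)


def to_obo(dag: GoDag) -> str:
    """Serialise a DAG as a minimal OBO document (is_a edges only)."""
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for tid in dag.term_ids:
        term = dag.term(tid)
        lines += ["[Term]", f"id: {tid}", f"name: {term.name}",
                  f"namespace: {term.namespace}"]
        for p in dag.parents(tid):
            lines.append(f"is_a: {p} ! {dag.term(p).name}")
        lines.append("")
    return "\n".join(lines)
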