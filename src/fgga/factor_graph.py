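"""Core factor graph over an ontology DAG.

Each ontology term becomes a binary variable node x_i (1 = annotated,
0 = not annotated; internally the noise channel uses the +1/-1 encoding).
Each non-root term contributes one logical factor linking the term (child)
to all of its is_a parents.  The factor encodes the true-path-graph
constraint through two rules: a positive child implies positive parents
(r1), and a negative parent implies negative children (r2).  Equivalently
the factor is 0 exactly when the child is 1 and at least one parent is 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UnknownTermError
from .ontology import GoDag

#: Truth tables are materialised only up to this factor degree (child +
#: parents); beyond it the closed-form predicate is used.
MAX_TABLE_DEGREE = 12


def labels_to_spin(labels):
    """Map {1, 0} annotation labels to the {+1, -1} channel encoding."""
    arr = np.asarray(labels)
    return 2 * arr - 1


def spin_to_labels(spin):
    """Inverse of :func:`labels_to_spin`."""
    arr = np.asarray(spin)
    return ((arr + 1) // 2).astype(arr.dtype)


@dataclass(frozen=True)
class LogicalFactor:
    """TPG constraint factor for one child term and its is_a parents."""

    child: str
    parents: tuple[str, ...]

    def __post_init__(self):
        if not self.parents:
            raise ValueError(f"factor for {self.child!r} needs >= 1 parent")
        if self.child in self.parents:
            raise ValueError(f"{self.child!r} cannot be its own parent")

    @property
    def degree(self) -> int:
        return 1 + len(self.parents)

    @property
    def variables(self) -> tuple[str, ...]:
        """Linked variables in truth-table column order: parents, then child."""
        return self.parents + (self.child,)

    def evaluate(self, assignment: Mapping[str, int]) -> int:
        """0 iff child=1 and some parent=0, else 1."""
        if set(assignment) != set(self.variables):
            raise ValueError(
                f"assignment keys {sorted(assignment)} do not match factor "
                f"variables {sorted(self.variables)}"
            )
        if assignment[self.child] == 1:
            return int(all(assignment[p] == 1 for p in self.parents))
        return 1

    def truth_table(self) -> np.ndarray:
        """Explicit truth table, one row per assignment.

        Columns are the factor variables (parents first, child last) followed
        by the factor value; rows enumerate assignments in binary counting
        order with the child as least-significant bit.
        """
        if self.degree > MAX_TABLE_DEGREE:
            raise ValueError(
                f"degree {self.degree} exceeds table limit {MAX_TABLE_DEGREE}; "
                "use evaluate()"
            )
        rows = []
        for bits in itertools.product((0, 1), repeat=self.degree):
            assignment = dict(zip(self.variables, bits))
            rows.append(bits + (self.evaluate(assignment),))
        return np.array(rows, dtype=np.int8)


def evaluate_logical_factor(
    factor: LogicalFactor, assignment: Mapping[str, int]
) -> int:
    """Functional alias for :meth:`LogicalFactor.evaluate`."""
    return factor.evaluate(assignment)


@dataclass
class FactorGraph:
    """Bipartite graph of term variables, TPG factors and channel factors.

    ``variances`` and ``observations`` are optional until the graph is
    enriched with classifier scores; every observed variable then has a
    Gaussian-channel factor with the matching per-term variance.
    """

    variables: tuple[str, ...]
    logical_factors: tuple[LogicalFactor, ...]
    variances: pd.Series | None = None
    observations: pd.DataFrame | None = field(default=None)

    def __post_init__(self):
        varset = set(self.variables)
        children = [f.child for f in self.logical_factors]
        if len(set(children)) != len(children):
            raise ValueError("more than one logical factor for a child term")
        for f in self.logical_factors:
            if not set(f.variables) <= varset:
                raise ValueError(f"factor {f.child!r} links unknown variables")

    def enrich(self, observations: pd.DataFrame, variances: pd.Series) -> "FactorGraph":
        """Attach per-term scores and channel variances (observed leaves)."""
        obs = observations.reindex(columns=list(self.variables))
        var = variances.reindex(list(self.variables))
        if obs.isna().any().any():
            missing = [c for c in self.variables if observations.get(c) is None]
            raise ValueError(f"missing observations for terms {missing[:5]}")
        if var.isna().any():
            raise ValueError("missing variance for some terms")
        return FactorGraph(self.variables, self.logical_factors, var, obs)

    def to_graphml(self) -> str:
        """GraphML rendering of the bipartite structure, for inspection."""
        import networkx as nx

        g = nx.Graph()
        for v in self.variables:
            g.add_node(v, kind="variable")
        for f in self.logical_factors:
            fid = f"f[{f.child}]"
            g.add_node(fid, kind="logical_factor")
            for v in f.variables:
                g.add_edge(fid, v)
        if self.variances is not None:
            for v in self.variables:
                gid = f"g[{v}]"
                g.add_node(gid, kind="channel_factor", variance=float(self.variances[v]))
                g.add_edge(gid, v)
        return "\n".join(nx.generate_graphml(g))


def build_core_fg(dag: GoDag) -> FactorGraph:
    """Match a rooted DAG to its core factor graph.

    One logical factor per non-root term, spanning the term and all of its
    parents.  The factor set depends only on the edge set, so the result is
    deterministic and independent of traversal order.
    """
    factors = tuple(
        LogicalFactor(child=t, parents=dag.parents(t))
        for t in dag.term_ids
        if t != dag.root
    )
    return FactorGraph(variables=dag.term_ids, logical_factors=factors)


def check_consistency(dag: GoDag, labels: Mapping[str, int]) -> list[tuple[str, str]]:
    """Return every (child, parent) edge with child=1 and parent=0.

    An empty list means the labelling satisfies the TPG constraint.
    """
    missing = [t for t in dag.term_ids if t not in labels]
    if missing:
        raise UnknownTermError(f"labels missing term {missing[0]!r}")
    return [
        (c, p) for c, p in dag.edges if labels[c] == 1 and labels[p] == 0
    ]


def repair_labels(dag: GoDag, labels: Mapping[str, int]) -> dict[str, int]:
    """Make a labelling TPG-consistent by top-down negative propagation.

    Processing terms from the root downward, a child is forced to 0 whenever
    any parent ended up 0 (rule r2 applied transitively).  Positives of the
    output are a subset of positives of the input; consistent inputs pass
    through unchanged.
    """
    missing = [t for t in dag.term_ids if t not in labels]
    if missing:
        raise UnknownTermError(f"labels missing term {missing[0]!r}")
    out: dict[str, int] = {}
    for t in dag.topological_order():
        v = int(labels[t])
        if t != dag.root and any(out[p] == 0 for p in dag.parents(t)):
            v = 0
        out[t] = v
    return out


def repair_matrix(dag: GoDag, labels: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`repair_labels` over a samples x terms frame."""
    out = labels.astype("int8").copy()
    for t in dag.topological_order():
        if t == dag.root:
            continue
        for p in dag.parents(t):
            out[t] &= out[p]
    return out


def truth_table_tsv(factor: LogicalFactor) -> str:
    """Tab-separated dump of a factor's truth table (parents, child, value)."""
    header = list(factor.variables) + [f"f[{factor.child}]"]
    lines = ["\t".join(header)]
    for row in factor.truth_table():
        lines.append("\t".join(str(int(v)) for v in row))
    return "\n".join(lines)
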