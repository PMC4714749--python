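"""Gene Ontology structure and annotation handling.

The ontology is modelled as a rooted DAG of terms connected by ``is_a``
edges oriented child -> parent.  Annotations obey the true-path-graph (TPG)
rule: a gene annotated to a term is implicitly annotated to every ancestor
of that term, up to the root of the domain.  This module reads OBO and
GAF-style inputs, applies evidence-code policies, propagates annotations to
ancestors (``ancestor_closure``) and selects well-supported sub-DAGs.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

from .errors import OntologyStructureError, UnknownTermError

logger = logging.getLogger(__name__)

#: GO experimental evidence codes accepted under the *robust* policy.
ROBUST_EVIDENCE = frozenset({"IMP", "IGI", "IPI", "IEP", "IDA"})
#: The *loose* policy additionally accepts author statements and electronic
#: annotations.
LOOSE_EVIDENCE = ROBUST_EVIDENCE | {"TAS", "IEA"}

EVIDENCE_POLICIES: Mapping[str, frozenset[str]] = {
    "robust": ROBUST_EVIDENCE,
    "loose": frozenset(LOOSE_EVIDENCE),
}


@dataclass(frozen=True)
class GoTerm:
    """A single ontology term."""

    id: str
    name: str = ""
    namespace: str = ""


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene -> term annotation with its evidence code."""

    gene: str
    term: str
    evidence: str


class GoDag:
    """Rooted DAG of :class:`GoTerm` with ``is_a`` edges child -> parent.

    Invariants enforced at construction: the graph is acyclic, has exactly
    one root (a term with no parents), and every term reaches the root by
    directed child -> parent paths.
    """

    def __init__(self, terms: Iterable[GoTerm], edges: Iterable[tuple[str, str]]):
        self._terms: dict[str, GoTerm] = {}
        for t in terms:
            if t.id in self._terms:
                raise OntologyStructureError(f"duplicate term id {t.id!r}")
            self._terms[t.id] = t
        g = nx.DiGraph()
        g.add_nodes_from(self._terms)
        for child, parent in edges:
            for tid in (child, parent):
                if tid not in self._terms:
                    raise UnknownTermError(f"edge references unknown term {tid!r}")
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyStructureError(
                f"is_a cycle detected, e.g. edge {cycle[0][0]} -> {cycle[0][1]}"
            )
        roots = sorted(n for n in g if g.out_degree(n) == 0)
        if not roots:
            raise OntologyStructureError("no root term found")
        if len(roots) > 1:
            raise OntologyStructureError(f"multiple roots found: {roots}")
        self.root: str = roots[0]
        orphans = sorted(set(g) - nx.ancestors(g, self.root) - {self.root})
        if orphans:
            raise OntologyStructureError(
                f"terms not connected to the root {self.root}: {orphans[:5]}"
            )
        self._graph = g
        self.term_ids: tuple[str, ...] = tuple(sorted(self._terms))

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def term(self, term_id: str) -> GoTerm:
        try:
            return self._terms[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown term {term_id!r}") from None

    @property
    def edges(self) -> list[tuple[str, str]]:
        """All (child, parent) is_a pairs, sorted."""
        return sorted(self._graph.edges())

    def parents(self, term_id: str) -> tuple[str, ...]:
        self.term(term_id)
        return tuple(sorted(self._graph.successors(term_id)))

    def children(self, term_id: str) -> tuple[str, ...]:
        self.term(term_id)
        return tuple(sorted(self._graph.predecessors(term_id)))

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable by child -> parent paths (excluding the term)."""
        self.term(term_id)
        return frozenset(nx.descendants(self._graph, term_id))

    def descendants(self, term_id: str) -> frozenset[str]:
        self.term(term_id)
        return frozenset(nx.ancestors(self._graph, term_id))

    def topological_order(self) -> list[str]:
        """Terms ordered root first, every parent before its children.

        Deterministic: ties are broken lexicographically.
        """
        order = list(
            nx.lexicographical_topological_sort(self._graph.reverse(copy=False))
        )
        return order

    def subdag(self, term_ids: Iterable[str]) -> "GoDag":
        keep = set(term_ids)
        missing = keep - set(self._terms)
        if missing:
            raise UnknownTermError(f"unknown term {sorted(missing)[0]!r}")
        terms = [self._terms[t] for t in sorted(keep)]
        edges = [(c, p) for c, p in self._graph.edges() if c in keep and p in keep]
        return GoDag(terms, edges)

    def __repr__(self) -> str:
        return (
            f"GoDag({len(self)} terms, {self._graph.number_of_edges()} edges, "
            f"root={self.root})"
        )


# ---------------------------------------------------------------------------
# OBO / GAF input
# ---------------------------------------------------------------------------

def parse_obo(stream, namespace: str | None = None) -> GoDag:
    """Read an OBO document into a :class:`GoDag`.

    Only ``id``, ``name``, ``namespace``, ``is_a`` and ``is_obsolete`` stanza
    tags are interpreted; obsolete terms and non-``is_a`` relationships
    (``part_of``, ``regulates``, ...) are dropped.  The result is restricted
    to a single namespace: pass ``namespace`` explicitly when the document
    mixes GO domains.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    graph = obonet.read_obo(stream)  # ignores obsolete terms by default

    namespaces = {d.get("namespace", "") for _, d in graph.nodes(data=True)}
    if namespace is None:
        if len(namespaces) > 1:
            raise OntologyStructureError(
                f"document mixes namespaces {sorted(namespaces)}; pass namespace="
            )
        namespace = next(iter(namespaces)) if namespaces else ""

    node_ids = {
        n for n, d in graph.nodes(data=True) if d.get("namespace", "") == namespace
    }
    if not node_ids:
        raise OntologyStructureError(f"no terms in namespace {namespace!r}")
    terms = [
        GoTerm(n, graph.nodes[n].get("name", ""), namespace) for n in sorted(node_ids)
    ]
    edges = [
        (u, v)
        for u, v, key in graph.edges(keys=True)
        if key == "is_a" and u in node_ids and v in node_ids
    ]
    return GoDag(terms, edges)


def read_gaf(stream) -> list[AnnotationRecord]:
    """Read GAF 2.x tab-separated annotation lines.

    Comment lines start with ``!``.  Rows whose qualifier column contains
    ``NOT`` are negated annotations and are dropped.  Columns used: DB object
    id (2), qualifier (4), GO id (5), evidence code (7).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[AnnotationRecord] = []
    dropped_not = 0
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 7:
            raise ValueError(f"GAF row with {len(cols)} columns: {line[:60]!r}")
        if "NOT" in cols[3].split("|"):
            dropped_not += 1
            continue
        records.append(AnnotationRecord(gene=cols[1], term=cols[4], evidence=cols[6]))
    if dropped_not:
        logger.info("dropped %d NOT-qualified GAF rows", dropped_not)
    return records


def apply_evidence_policy(
    records: Sequence[AnnotationRecord], policy: str
) -> list[AnnotationRecord]:
    """Keep records whose evidence code is accepted by *policy*.

    ``robust`` keeps the experimental codes IMP, IGI, IPI, IEP, IDA;
    ``loose`` additionally keeps TAS and IEA.  Input order is preserved.
    """
    try:
        accepted = EVIDENCE_POLICIES[policy]
    except KeyError:
        raise ValueError(
            f"unknown policy {policy!r}; expected one of {sorted(EVIDENCE_POLICIES)}"
        ) from None
    return [r for r in records if r.evidence in accepted]


# ---------------------------------------------------------------------------
# Annotation matrices
# ---------------------------------------------------------------------------

def ancestor_closure(
    dag: GoDag,
    records: Sequence[AnnotationRecord],
    on_missing: str = "raise",
) -> pd.DataFrame:
    """Propagate direct annotations to all ancestors (TPG closure).

    Returns a genes x terms binary DataFrame where an entry is 1 iff the
    gene is annotated to the term or to any of its descendants.  The output
    is ancestor-closed by construction.

    ``on_missing='raise'`` errors on records naming terms absent from *dag*;
    ``'drop'`` discards them with a logged count.
    """
    if on_missing not in ("raise", "drop"):
        raise ValueError(f"on_missing must be 'raise' or 'drop', got {on_missing!r}")
    up: dict[str, frozenset[str]] = {
        t: dag.ancestors(t) | {t} for t in dag.term_ids
    }
    per_gene: dict[str, set[str]] = {}
    dropped = 0
    for rec in records:
        if rec.term not in dag:
            if on_missing == "raise":
                raise UnknownTermError(f"annotation to unknown term {rec.term!r}")
            dropped += 1
            continue
        per_gene.setdefault(rec.gene, set()).update(up[rec.term])
    if dropped:
        logger.info("dropped %d annotations to terms outside the DAG", dropped)
    genes = sorted(per_gene)
    mat = pd.DataFrame(0, index=genes, columns=list(dag.term_ids), dtype="int8")
    for g in genes:
        mat.loc[g, sorted(per_gene[g])] = 1
    return mat


def is_ancestor_closed(dag: GoDag, matrix: pd.DataFrame) -> bool:
    """True iff no gene has a positive child with a negative parent."""
    for child, parent in dag.edges:
        if child in matrix.columns and parent in matrix.columns:
            if ((matrix[child] == 1) & (matrix[parent] == 0)).any():
                return False
    return True


def select_subdag(dag: GoDag, matrix: pd.DataFrame, min_pos: int) -> GoDag:
    """Induced sub-DAG on terms with >= *min_pos* positive genes.

    Counts are taken on the (closure) matrix columns; the kept set is made
    ancestor-closed and always includes the root, so the result is a valid
    rooted DAG.  Closure makes column sums monotone non-decreasing from
    child to parent, hence keeping a child always keeps its parents.
    """
    if min_pos < 1:
        raise ValueError(f"min_pos must be >= 1, got {min_pos}")
    unknown = set(matrix.columns) - set(dag.term_ids)
    if unknown:
        raise UnknownTermError(f"unknown term {sorted(unknown)[0]!r}")
    counts = matrix.sum(axis=0)
    keep = {t for t in matrix.columns if counts[t] >= min_pos}
    closed = set(keep)
    for t in keep:
        closed |= dag.ancestors(t)
    closed.add(dag.root)
    return dag.subdag(closed)


# ---------------------------------------------------------------------------
# Tab-separated import/export
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene").rename_axis(None)
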