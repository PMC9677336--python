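"""Slim maps: rolling specific ontology terms up to general search facets.

Different submitters map the same concept to terms of very different
specificity (an anatomy ontology offers tens of thousands of terms, many
separated by subtle shades of meaning), so searching on raw terms fragments
recall.  A *slim* is a small, user-supplied set of general terms; each
specific term is mapped to its minimal slim ancestors over the vocabulary's
``is_a`` DAG, and the catalog can then facet on raw terms, slim terms, or
both, without losing access to any record.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import networkx as nx

from . import errors
from .errors import C2M2Error

#: Facet bucket for terms the slim does not cover.
UNCLASSIFIED = "unclassified"


class OntologyDag:
    """An ``is_a`` DAG for one vocabulary (edges run child -> parent)."""

    def __init__(self, vocabulary, edges=(), nodes=()):
        self.vocabulary = vocabulary
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(nodes)
        self.graph.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError(f"{vocabulary} is_a graph contains a cycle")

    @property
    def nodes(self):
        return set(self.graph.nodes)

    def __contains__(self, term):
        return term in self.graph

    @classmethod
    def read(cls, path, vocabulary):
        """Read a child/parent edge-list TSV."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        if not lines or tuple(lines[0].split("\t")) != ("child", "parent"):
            raise C2M2Error(errors.BAD_HEADER,
                            f"DAG file {path} must have columns child, parent")
        edges = [tuple(line.split("\t")) for line in lines[1:]]
        return cls(vocabulary, edges=edges)

    def write(self, path):
        lines = ["child\tparent"]
        for child, parent in sorted(self.graph.edges):
            lines.append(f"{child}\t{parent}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class SlimMap:
    """A slim-term set for one vocabulary."""

    vocabulary: str
    slim_terms: frozenset = dc_field(default_factory=frozenset)

    @classmethod
    def read(cls, path):
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        if not lines or tuple(lines[0].split("\t")) != ("vocabulary", "slim_term"):
            raise C2M2Error(errors.BAD_HEADER,
                            f"slim file {path} must have columns vocabulary, slim_term")
        vocab = None
        terms = set()
        for line in lines[1:]:
            vocab, term = line.split("\t")
            terms.add(term)
        return cls(vocabulary=vocab or "", slim_terms=frozenset(terms))

    def write(self, path):
        lines = ["vocabulary\tslim_term"]
        for term in sorted(self.slim_terms):
            lines.append(f"{self.vocabulary}\t{term}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def ancestors(dag, term):
    """Transitive ``is_a`` closure above ``term`` (term itself excluded)."""
    if term not in dag:
        raise C2M2Error(errors.UNKNOWN_TERM,
                        f"term {term!r} not in the {dag.vocabulary} DAG")
    # Edges run child -> parent, so graph-descendants are ontology ancestors.
    return set(nx.descendants(dag.graph, term))


def map_to_slim(dag, slim, term):
    """Minimal slim ancestors of ``term``, in sorted order.

    A slim term s qualifies when s is ``term`` itself or an ancestor of it,
    and no other qualifying slim term lies strictly below s (i.e. the most
    specific slim hits are kept).  Multiple minimal ancestors are all
    returned — recall matters more than a unique facet.  Terms the slim
    does not cover map to the empty tuple.
    """
    slim_terms = slim.slim_terms if isinstance(slim, SlimMap) else frozenset(slim)
    candidates = ({term} | ancestors(dag, term)) & slim_terms
    minimal = []
    for s in candidates:
        if not any(s in ancestors(dag, other) for other in candidates if other != s):
            minimal.append(s)
    return tuple(sorted(minimal))


def slim_mapping(dag, slim, terms):
    """Map each of ``terms`` to its slim image: term -> tuple of slim terms."""
    return {term: map_to_slim(dag, slim, term) for term in terms}


def annotate_package_slims(pkg, dags, slims):
    """Slim-annotation rows for every CV term used in ``pkg``.

    ``dags`` and ``slims`` map vocabulary name -> OntologyDag / SlimMap.
    Returns rows ``{vocabulary, term, slim_term}``, one per (term, slim
    image element); unmapped terms land in the reserved ``unclassified``
    bucket, and vocabularies without a DAG/slim are skipped.  Unknown terms
    (absent from their DAG) propagate UNKNOWN_TERM.
    """
    from .vocab import collect_used_terms  # local import, avoids a cycle

    used = collect_used_terms(pkg, pkg.registry, issues=[])
    rows = []
    for vocabulary in sorted(used):
        if vocabulary not in dags or vocabulary not in slims:
            continue
        dag, slim = dags[vocabulary], slims[vocabulary]
        for term in sorted(used[vocabulary]):
            image = map_to_slim(dag, slim, term)
            if not image:
                rows.append({"vocabulary": vocabulary, "term": term,
                             "slim_term": UNCLASSIFIED})
            for s in image:
                rows.append({"vocabulary": vocabulary, "term": term,
                             "slim_term": s})
    return rows
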