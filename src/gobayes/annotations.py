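"""GO ontology parsing, annotation propagation, and the term-to-genes file.

Gene-to-term associations are propagated upward through the GO DAG
(is_a and part_of), but only as far as the highest ancestor on each
path that already carries a manual (non-electronic) direct annotation.
Stopping at curated levels keeps the propagated table at a level of
abstraction that biologists have judged informative, instead of
flooding the uninformative near-root terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import obonet
from Bio.UniProt import GOA

__all__ = [
    "OntologyGraph",
    "AnnotationTable",
    "load_obo",
    "load_associations",
    "propagate",
    "write_annotation_file",
    "read_annotation_file",
    "NONMANUAL_EVIDENCE",
]

RELATIONS = ("is_a", "part_of")
#: Evidence codes that do not count as manual curation for the stop rule.
NONMANUAL_EVIDENCE = frozenset({"IEA", "ND"})


@dataclass
class OntologyGraph:
    """GO DAG restricted to is_a / part_of, child -> parent edges."""

    graph: nx.MultiDiGraph

    @property
    def nodes(self):
        return self.graph.nodes

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def parents(self, term: str) -> list[tuple[str, str]]:
        """(parent, relation) pairs for the traversed relation types."""
        return [
            (v, key)
            for _, v, key in self.graph.out_edges(term, keys=True)
        ]

    def ancestor_paths(self, term: str) -> Iterator[list[str]]:
        """Every maximal upward path starting at ``term`` (term excluded).

        Paths follow is_a/part_of child->parent edges up to a root.  The
        DAG guarantees termination; GO-like graphs keep the path count
        manageable.
        """
        stack: list[tuple[str, list[str]]] = [(term, [])]
        while stack:
            node, path = stack.pop()
            parents = [p for p, _ in self.parents(node)]
            if not parents:
                if path:
                    yield path
                continue
            for p in parents:
                stack.append((p, path + [p]))


def load_obo(path) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 ontology.

    Keeps is_a and part_of relations only; obsolete stanzas are
    excluded.  Raises on a cycle over the retained relations.
    """
    try:
        raw = obonet.read_obo(path)  # skips obsolete stanzas
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise ValueError(f"failed to parse OBO file {path}: {exc}") from exc
    g = nx.MultiDiGraph()
    for node, attrs in raw.nodes(data=True):
        g.add_node(node, name=attrs.get("name"), namespace=attrs.get("namespace"))
    for u, v, key in raw.edges(keys=True):
        if key in RELATIONS and u in g and v in g:
            g.add_edge(u, v, key=key)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"ontology contains a cycle over {RELATIONS}: {cycle}")
    return OntologyGraph(g)


def _parse_gaf(path) -> list[tuple[str, str, str]]:
    out = []
    with open(path, encoding="utf-8") as handle:
        for i, rec in enumerate(GOA.gafiterator(handle), start=1):
            try:
                gene = rec["DB_Object_ID"]
                term = rec["GO_ID"]
                code = rec["Evidence"]
                qualifiers = rec.get("Qualifier", [])
            except (KeyError, TypeError) as exc:
                raise ValueError(f"malformed GAF record at row {i}: {exc}") from exc
            if not gene or not term:
                raise ValueError(f"malformed GAF record at row {i}: empty field")
            if any(q.split("|")[0] == "NOT" or q == "NOT" for q in qualifiers):
                continue
            out.append((gene, term, code or "NA"))
    return out


def _parse_tsv(path) -> list[tuple[str, str, str]]:
    out = []
    with open(path, encoding="utf-8") as handle:
        for i, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"malformed association row {i}: expected 2 tab-separated "
                    f"fields, got {len(fields)}"
                )
            out.append((fields[0], fields[1], "NA"))
    return out


def load_associations(path, format: str = "gaf") -> list[tuple[str, str, str]]:
    """Load gene-to-term associations as (gene_id, term_id, evidence_code).

    GAF 2.x rows with a NOT qualifier are dropped; two-column TSV input
    gets evidence code "NA" (treated as manual for the propagation stop
    rule, since no code information exists).
    """
    if format == "gaf":
        return _parse_gaf(path)
    if format == "tsv":
        return _parse_tsv(path)
    raise ValueError(f"unknown association format {format!r}; use 'gaf' or 'tsv'")


@dataclass
class AnnotationTable:
    """Map term -> annotated genes, with per-pair provenance."""

    terms: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, term: str, gene: str, source: str = "direct") -> None:
        genes = self.terms.setdefault(term, set())
        genes.add(gene)
        # direct wins over propagated if a pair arrives through both routes
        if self.provenance.get((term, gene)) != "direct":
            self.provenance[(term, gene)] = source

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return {t: g for t, g in self.terms.items() if g} == {
            t: g for t, g in other.terms.items() if g
        }

    def nonempty_terms(self) -> dict[str, set[str]]:
        return {t: g for t, g in self.terms.items() if g}


def propagate(
    graph: OntologyGraph,
    direct: Iterable[tuple[str, str, str]],
    namespace: str | None = "biological_process",
) -> AnnotationTable:
    """Propagate direct annotations upward with the curated-level stop rule.

    Along every upward path from a gene's direct term, the gene is added
    to each ancestor at or below the highest ancestor possessing at
    least one direct manual annotation (evidence code outside
    ``NONMANUAL_EVIDENCE``); ancestors above that stopping term receive
    nothing, and a path with no manually annotated ancestor contributes
    nothing.  Restricted to one namespace when given.
    """
    direct = list(direct)
    known = [
        (g, t, c)
        for g, t, c in direct
        if t in graph.nodes
        and (namespace is None or graph.namespace(t) == namespace)
    ]
    skipped = {t for g, t, c in direct if t not in graph.nodes}
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} association term(s) absent from the "
            f"ontology: {', '.join(sorted(skipped)[:5])}"
            + ("..." if len(skipped) > 5 else ""),
            RuntimeWarning,
            stacklevel=2,
        )

    manual_terms = {t for _, t, c in known if c not in NONMANUAL_EVIDENCE}

    table = AnnotationTable()
    for gene, term, _code in known:
        table.add(term, gene, "direct")

    in_ns = lambda t: namespace is None or graph.namespace(t) == namespace
    for gene, term, _code in known:
        for path in graph.ancestor_paths(term):
            stop = max(
                (i for i, anc in enumerate(path) if anc in manual_terms),
                default=None,
            )
            if stop is None:
                continue
            for anc in path[: stop + 1]:
                if in_ns(anc):
                    table.add(anc, gene, "propagated")
    return table


def write_annotation_file(table: AnnotationTable, path) -> None:
    """Write the term-to-genes TSV: term id, then its genes, tab-separated.

    Terms are written in lexicographic order with genes sorted within a
    line, so repeated writes are byte-identical; empty terms are omitted
    with a warning.
    """
    empty = sorted(t for t, g in table.terms.items() if not g)
    if empty:
        warnings.warn(
            f"omitting {len(empty)} term(s) with no genes: "
            + ", ".join(empty[:5]) + ("..." if len(empty) > 5 else ""),
            RuntimeWarning,
            stacklevel=2,
        )
    with open(path, "w", encoding="utf-8") as handle:
        for term in sorted(table.nonempty_terms()):
            genes = sorted(table.terms[term])
            handle.write("\t".join([term, *genes]) + "\n")


def read_annotation_file(path) -> AnnotationTable:
    """Read the term-to-genes TSV written by :func:`write_annotation_file`."""
    table = AnnotationTable()
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for i, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            term, genes = fields[0], fields[1:]
            if term in seen:
                raise ValueError(f"duplicate term line for {term!r} at row {i}")
            seen.add(term)
            for g in genes:
                if g:
                    table.add(term, g, "direct")
    return table
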