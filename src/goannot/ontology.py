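"""Gene Ontology DAG: OBO parsing, ancestor closure, aspects and slim mapping.

The ontology layer serves every other module: the transfer rules need
aspect lookup (molecular function / biological process / cellular
component), the slim chart needs the minimal-cover mapping of a term onto
a set of high-level "slim" terms, and GAF validation needs obsolete-term
and alt_id resolution.

Only a deliberately small OBO 1.2/1.4 subset is interpreted: ``[Term]``
stanzas with ``id``, ``name``, ``namespace``, ``is_a``,
``relationship: part_of``, ``is_obsolete`` and ``alt_id`` tags.  Closure
operations traverse is_a and part_of edges only; regulates-type
relationships are parsed but ignored with a logged warning, which is the
conventional GO-slim closure.  Obsolete terms are retained so annotation
validation can flag them, but they never participate in closure or slim
mapping.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx

from goannot.errors import LookupFailure, ParseError, ValidationError

logger = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"^GO:\d{7}$")

#: OBO namespace tag -> single-letter aspect used in GAF column 9.
NAMESPACE_TO_ASPECT = {
    "molecular_function": "F",
    "biological_process": "P",
    "cellular_component": "C",
}

CLOSURE_RELATIONS = frozenset({"is_a", "part_of"})


@dataclass
class GOTerm:
    """One GO term.

    ``parents`` holds ``(relation, parent_id)`` pairs restricted to the
    relations this package traverses (is_a, part_of). For obsolete terms
    the parent list is always empty: an obsolete term has no place in the
    live DAG.
    """

    id: str
    name: str = ""
    aspect: str | None = None  # F, P or C; None only for obsolete terms
    parents: list[tuple[str, str]] = field(default_factory=list)
    obsolete: bool = False
    alt_ids: list[str] = field(default_factory=list)

    def parent_ids(self, relations: Iterable[str] = CLOSURE_RELATIONS) -> list[str]:
        rels = set(relations)
        return [p for rel, p in self.parents if rel in rels]


class Ontology:
    """The GO DAG with alt_id resolution and cached closure queries."""

    def __init__(self, terms: dict[str, GOTerm]):
        self.terms: dict[str, GOTerm] = terms
        self._alt: dict[str, str] = {}
        for term in terms.values():
            for alt in term.alt_ids:
                self._alt[alt] = term.id
        self.roots: dict[str, str] = {}  # aspect -> root accession
        for term in terms.values():
            if not term.obsolete and not term.parents and term.aspect:
                # a non-obsolete parentless term is an aspect root
                self.roots.setdefault(term.aspect, term.id)
        self._ancestor_cache: dict[tuple[str, frozenset[str]], frozenset[str]] = {}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str:
        """Map an accession (primary or alt_id) to its primary accession."""
        if term_id in self.terms:
            return term_id
        if term_id in self._alt:
            return self._alt[term_id]
        raise LookupFailure(f"unknown GO term: {term_id}")

    def term(self, term_id: str) -> GOTerm:
        return self.terms[self.resolve(term_id)]

    def ancestors(
        self, term_id: str, relations: Iterable[str] = CLOSURE_RELATIONS
    ) -> set[str]:
        """Transitive closure over the selected relations, excluding the term.

        Obsolete terms have no parents, hence an empty closure.
        """
        start = self.resolve(term_id)
        rels = frozenset(relations)
        if not rels <= CLOSURE_RELATIONS:
            raise ValueError(f"unsupported closure relations: {rels - CLOSURE_RELATIONS}")
        key = (start, rels)
        cached = self._ancestor_cache.get(key)
        if cached is not None:
            return set(cached)
        out: set[str] = set()
        stack = [start]
        while stack:
            node = stack.pop()
            for parent in self.terms[node].parent_ids(rels):
                if parent not in out:
                    out.add(parent)
                    stack.append(parent)
        self._ancestor_cache[key] = frozenset(out)
        return out

    def aspect_of(self, term_id: str) -> str:
        """Aspect (F/P/C) of the term's unique is_a root."""
        term = self.term(term_id)
        if term.obsolete:
            raise LookupFailure(f"term {term.id} is obsolete; aspect undefined")
        assert term.aspect is not None
        return term.aspect

    def is_ancestor(self, candidate: str, term_id: str) -> bool:
        """True iff ``candidate`` is a (strict) is_a/part_of ancestor of ``term_id``."""
        return self.resolve(candidate) in self.ancestors(term_id)


@dataclass
class SlimSet:
    """A named set of high-level GO terms used to bin annotations."""

    name: str
    term_ids: set[str]

    def validate(self, ontology: Ontology) -> None:
        for tid in self.term_ids:
            term = ontology.term(tid)  # raises LookupFailure if unknown
            if term.obsolete:
                raise ValidationError(f"slim '{self.name}' contains obsolete term {tid}")


def parse_obo(stream: IO[str]) -> Ontology:
    """Parse an OBO 1.2/1.4 text stream into an :class:`Ontology`.

    Only ``[Term]`` stanzas are interpreted; every other stanza type
    (``[Typedef]`` ...) is skipped. Raises :class:`ParseError` for a
    stanza missing its ``id``, or missing ``namespace`` on a non-obsolete
    term, and :class:`ValidationError` (listing one cycle) if the is_a
    graph is cyclic.
    """
    terms: dict[str, GOTerm] = {}
    stanza: list[str] | None = None
    stanza_type: str | None = None

    def flush() -> None:
        if stanza_type != "Term" or stanza is None:
            return
        term = _parse_term_stanza(stanza)
        if term.id in terms:
            raise ParseError(f"duplicate term stanza for {term.id}")
        terms[term.id] = term

    for raw in stream:
        line = raw.rstrip("\n")
        if line.startswith("["):
            flush()
            stanza_type = line.strip("[]").strip()
            stanza = []
        elif stanza is not None and line.strip():
            stanza.append(line)
    flush()

    _check_acyclic(terms)
    ontology = Ontology(terms)
    _check_rooted(ontology)
    return ontology


def _parse_term_stanza(lines: list[str]) -> GOTerm:
    tags: list[tuple[str, str]] = []
    for line in lines:
        if line.startswith("!"):
            continue
        if ":" not in line:
            continue
        tag, _, value = line.partition(":")
        value = value.split(" ! ")[0].strip()  # strip trailing OBO comments
        tags.append((tag.strip(), value))
    tagmap = {tag: value for tag, value in tags}

    term_id = tagmap.get("id")
    if not term_id:
        head = lines[0] if lines else "<empty>"
        raise ParseError(f"[Term] stanza without id (near '{head}')")
    if not GO_ID_RE.match(term_id):
        raise ParseError(f"stanza {term_id}: id is not a GO accession")

    obsolete = tagmap.get("is_obsolete", "").strip().lower() == "true"
    namespace = tagmap.get("namespace")
    aspect = NAMESPACE_TO_ASPECT.get(namespace) if namespace else None
    if not obsolete and aspect is None:
        raise ParseError(f"stanza {term_id}: missing or unknown namespace")

    parents: list[tuple[str, str]] = []
    alt_ids: list[str] = []
    for tag, value in tags:
        if tag == "is_a":
            parents.append(("is_a", value))
        elif tag == "relationship":
            parts = value.split()
            if len(parts) >= 2 and parts[0] == "part_of":
                parents.append(("part_of", parts[1]))
            else:
                logger.warning(
                    "term %s: ignoring relationship of type %r",
                    term_id,
                    parts[0] if parts else value,
                )
        elif tag == "alt_id":
            alt_ids.append(value)

    if obsolete:
        parents = []  # obsolete terms never participate in closure
    return GOTerm(
        id=term_id,
        name=tagmap.get("name", ""),
        aspect=aspect,
        parents=parents,
        obsolete=obsolete,
        alt_ids=alt_ids,
    )


def _check_acyclic(terms: dict[str, GOTerm]) -> None:
    graph = nx.DiGraph()
    graph.add_nodes_from(terms)
    for term in terms.values():
        for parent in term.parent_ids({"is_a"}):
            if parent in terms:
                graph.add_edge(term.id, parent)
    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        return
    path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
    raise ValidationError(f"is_a graph is cyclic: {path}")


def _check_rooted(ontology: Ontology) -> None:
    for term in ontology.terms.values():
        if term.obsolete or not term.parents:
            continue
        root_aspects = {
            ontology.terms[a].aspect
            for a in ontology.ancestors(term.id, {"is_a"})
            if not ontology.terms[a].parents
        }
        if len(root_aspects) != 1:
            raise ValidationError(
                f"term {term.id} reaches {len(root_aspects)} aspect roots via is_a"
            )


def ancestors(
    ontology: Ontology, term_id: str, relations: Iterable[str] = CLOSURE_RELATIONS
) -> set[str]:
    """Functional alias for :meth:`Ontology.ancestors`."""
    return ontology.ancestors(term_id, relations)


def aspect_of(ontology: Ontology, term_id: str) -> str:
    """Functional alias for :meth:`Ontology.aspect_of`."""
    return ontology.aspect_of(term_id)


def map_to_slim(ontology: Ontology, term_id: str, slim: SlimSet) -> set[str]:
    """Minimal slim terms covering ``term_id``.

    A slim term covers the query if it is the query itself or an is_a/part_of
    ancestor of it. Of the covering slim terms only the most specific are
    returned: any covering slim term that has a covering descendant in the
    slim is dominated and dropped. The result is an antichain; it is empty
    when no slim term covers the query (tallied as "unmapped" by the slim
    chart).
    """
    primary = ontology.resolve(term_id)
    if ontology.terms[primary].obsolete:
        return set()
    covering = {
        s
        for s in slim.term_ids
        if s == primary or ontology.is_ancestor(s, primary)
    }
    return {
        s
        for s in covering
        if not any(other != s and ontology.is_ancestor(s, other) for other in covering)
    }


def read_slim(stream: IO[str], name: str = "slim") -> SlimSet:
    """Read a slim file: one GO accession per line, '#' comments allowed."""
    term_ids: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not GO_ID_RE.match(line):
            raise ParseError(f"not a GO accession: {line!r}", line=lineno)
        term_ids.add(line)
    return SlimSet(name=name, term_ids=term_ids)
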