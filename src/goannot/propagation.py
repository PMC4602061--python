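"""Phylogenetic annotation propagation over gene trees (PAINT-style).

Experimental annotations of characterized family members are overlaid on
a gene tree. A curator (or the MRCA heuristic in
:func:`propose_mrca_assertions`) asserts that a term represents an
ancient conserved function at an internal node; the assertion is recorded
as an IBD annotation ("inferred from biological aspect of descendant")
citing the supporting leaves, and the term is then propagated down to
every descendant leaf as an IBA annotation ("inferred from biological
aspect of ancestor") — except leaves that already hold the term
experimentally, leaves below a curator block (IKR: key residues, IRD:
rapid divergence), and leaves with an experimental NOT annotation to the
term, which acts as a single-leaf block.

Trees arrive as Newick with labeled internal nodes; leaves encode their
gene identity as ``TAXON|DB:GENEID`` (quoted in the Newick when the label
contains ``:``). Matching is exact-term: no ontology closure is applied
when deciding whether a leaf already holds a term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as _date
from typing import IO, Iterable, Sequence

import dendropy

from goannot.errors import ParseError, ValidationError
from goannot.gaf_io import Annotation, GafDocument, classify_evidence

logger = logging.getLogger(__name__)

#: db used for annotation subjects that are ancestral tree nodes. Such
#: nodes have no NCBI taxon; their records carry taxon:1 (taxonomy root).
ANCESTOR_DB = "TREE"


@dataclass(frozen=True)
class LeafIdentity:
    taxon_id: int
    db: str
    gene_id: str

    @property
    def subject(self) -> str:
        return f"{self.db}:{self.gene_id}"


@dataclass
class GeneTree:
    """Rooted gene tree with uniquely labeled nodes.

    ``parent`` maps each non-root label to its parent label; ``children``
    the reverse; ``leaves`` maps leaf labels to their parsed identities.
    ``preorder`` lists all labels root-first in parse order.
    """

    root: str
    parent: dict[str, str]
    children: dict[str, list[str]]
    leaves: dict[str, LeafIdentity]
    preorder: list[str]

    def __contains__(self, label: str) -> bool:
        return label in self.children or label in self.leaves

    def is_leaf(self, label: str) -> bool:
        return label in self.leaves

    def resolve_leaf(self, ref: str) -> str:
        """Resolve a leaf reference: full label or bare ``DB:GENEID`` token.

        The assertions TSV pipe-joins its supporter column, so supporters
        are written as the pipe-free ``DB:GENEID`` token; full labels are
        accepted anywhere in the API.
        """
        if ref in self.leaves:
            return ref
        for label, identity in self.leaves.items():
            if identity.subject == ref:
                return label
        raise ValidationError(f"unknown leaf reference {ref!r}")

    def descendant_leaves(self, label: str) -> list[str]:
        """Leaf labels under ``label`` (inclusive if itself a leaf), preorder."""
        out: list[str] = []
        stack = [label]
        order = {lab: i for i, lab in enumerate(self.preorder)}
        while stack:
            node = stack.pop()
            if self.is_leaf(node):
                out.append(node)
            else:
                stack.extend(reversed(self.children.get(node, [])))
        return sorted(out, key=order.__getitem__)

    def path(self, ancestor: str, leaf: str) -> list[str]:
        """Labels from ``ancestor`` down to ``leaf``, both inclusive."""
        chain = [leaf]
        node = leaf
        while node != ancestor:
            if node not in self.parent:
                raise ValidationError(f"{ancestor} is not an ancestor of {leaf}")
            node = self.parent[node]
            chain.append(node)
        return list(reversed(chain))

    def is_ancestor(self, ancestor: str, node: str) -> bool:
        while node in self.parent:
            if node == ancestor:
                return True
            node = self.parent[node]
        return node == ancestor

    def mrca(self, labels: Iterable[str]) -> str:
        """Most recent common ancestor of the given node labels."""
        labels = list(labels)
        if not labels:
            raise ValidationError("mrca of empty label set")

        def lineage(lab: str) -> list[str]:
            chain = [lab]
            while lab in self.parent:
                lab = self.parent[lab]
                chain.append(lab)
            return chain

        common = set(lineage(labels[0]))
        for lab in labels[1:]:
            common &= set(lineage(lab))
        # deepest common node = first along any lineage that is common
        for node in lineage(labels[0]):
            if node in common:
                return node
        raise ValidationError("labels do not share a root")  # pragma: no cover


@dataclass
class NodeAssertion:
    """Curator assertion that ``go_id`` is an ancestral function at a node."""

    node_label: str
    go_id: str
    supporting_leaves: list[str]


@dataclass
class PropagationBlock:
    """Curator block: the term does not propagate into this node's subtree."""

    node_label: str
    go_id: str
    reason: str  # IKR | IRD


@dataclass
class PropagationResult:
    ibd_records: list[Annotation] = field(default_factory=list)
    iba_records: list[Annotation] = field(default_factory=list)
    blocked_leaf_records: list[tuple[str, str, str]] = field(default_factory=list)


def _parse_leaf_label(label: str) -> LeafIdentity | None:
    if "|" not in label:
        return None
    taxon_text, _, rest = label.partition("|")
    if ":" not in rest:
        return None
    db, _, gene = rest.partition(":")
    try:
        return LeafIdentity(taxon_id=int(taxon_text), db=db, gene_id=gene)
    except ValueError:
        return None


def read_tree(stream: IO[str] | str) -> GeneTree:
    """Parse a Newick gene tree with ``TAXON|DB:GENEID`` leaf labels.

    Internal nodes without a label are auto-labeled ``ANC1``, ``ANC2``, ...
    in preorder. Duplicate labels and leaves without a parseable identity
    are errors.
    """
    text = stream if isinstance(stream, str) else stream.read()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"unparseable Newick: {exc}") from exc

    parent: dict[str, str] = {}
    children: dict[str, list[str]] = {}
    leaves: dict[str, LeafIdentity] = {}
    preorder: list[str] = []
    labels: dict[int, str] = {}
    seen: set[str] = set()
    counter = 0

    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon is not None else node.label
        if node.is_leaf():
            if label is None:
                raise ParseError("leaf without a label")
        elif not label:
            counter += 1
            label = f"ANC{counter}"
        if label in seen:
            raise ParseError(f"duplicate node label {label!r}")
        seen.add(label)
        labels[id(node)] = label
        preorder.append(label)
        if node.parent_node is not None:
            parent[label] = labels[id(node.parent_node)]
            children.setdefault(labels[id(node.parent_node)], []).append(label)
        if node.is_leaf():
            identity = _parse_leaf_label(label)
            if identity is None:
                raise ParseError(
                    f"leaf label {label!r} does not match the TAXON|DB:GENEID dialect"
                )
            leaves[label] = identity
        else:
            children.setdefault(label, [])

    root = preorder[0]
    return GeneTree(root=root, parent=parent, children=children, leaves=leaves, preorder=preorder)


def read_assertions(stream: IO[str]) -> list[NodeAssertion]:
    """Assertions TSV: node_label <tab> go_id <tab> pipe-joined supporter labels."""
    out: list[NodeAssertion] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise ParseError("expected 3 tab-separated columns", line=lineno)
        out.append(NodeAssertion(cols[0], cols[1], cols[2].split("|") if cols[2] else []))
    return out


def read_blocks(stream: IO[str]) -> list[PropagationBlock]:
    """Blocks TSV: node_label <tab> go_id <tab> reason (IKR or IRD)."""
    out: list[PropagationBlock] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise ParseError("expected 3 tab-separated columns", line=lineno)
        if cols[2] not in {"IKR", "IRD"}:
            raise ParseError(f"block reason must be IKR or IRD, got {cols[2]!r}", line=lineno)
        out.append(PropagationBlock(cols[0], cols[1], cols[2]))
    return out


def _experimental_by_leaf(
    tree: GeneTree, leaf_annotations: GafDocument
) -> tuple[dict[str, set[str]], dict[str, set[str]], dict[tuple[str, str], Annotation]]:
    """Per-leaf experimental positive and NOT term sets, plus a sample record."""
    by_subject = {identity.subject: label for label, identity in tree.leaves.items()}
    positive: dict[str, set[str]] = {}
    notted: dict[str, set[str]] = {}
    sample: dict[tuple[str, str], Annotation] = {}
    for ann in leaf_annotations.annotations:
        if classify_evidence(ann.evidence_code).method_class != "experimental":
            continue
        label = by_subject.get(ann.subject)
        if label is None:
            continue
        bucket = notted if ann.is_not else positive
        bucket.setdefault(label, set()).add(ann.go_id)
        sample.setdefault((label, ann.go_id), ann)
    return positive, notted, sample


def propagate(
    tree: GeneTree,
    leaf_annotations: GafDocument,
    assertions: Sequence[NodeAssertion],
    blocks: Sequence[PropagationBlock] = (),
    load_reference: str = "GO_REF:0000033",
    assigned_by: str = "goannot",
    run_date: str | None = None,
) -> PropagationResult:
    """Propagate asserted ancestral functions down the tree.

    For each assertion (node N, term T): one IBD record for N citing its
    supporting leaves, and one IBA record for every descendant leaf of N
    that (a) does not hold T experimentally, (b) has no block for T on the
    path N→leaf, and (c) has no experimental NOT annotation to T. Output
    order is (assertion order, preorder leaf order); blocked leaves are
    listed for audit with their reason (IKR/IRD, or NOT for leaf-level
    negative evidence).
    """
    run_date = run_date or _date.today().strftime("%Y%m%d")
    for block in blocks:
        if block.node_label not in tree:
            raise ValidationError(f"block names unknown node {block.node_label!r}")

    positive, notted, sample = _experimental_by_leaf(tree, leaf_annotations)
    blocks_by_term: dict[str, set[str]] = {}
    for block in blocks:
        blocks_by_term.setdefault(block.go_id, set()).add(block.node_label)
    block_reason = {(b.node_label, b.go_id): b.reason for b in blocks}

    result = PropagationResult()
    for assertion in assertions:
        node = assertion.node_label
        if node not in tree:
            raise ValidationError(f"assertion names unknown node {node!r}")
        if not assertion.supporting_leaves:
            raise ValidationError(f"assertion at {node} has no supporting leaves")
        supporters = [tree.resolve_leaf(s) for s in assertion.supporting_leaves]
        for leaf in supporters:
            if not tree.is_ancestor(node, leaf):
                raise ValidationError(
                    f"assertion node {node} is not ancestral to supporter {leaf}"
                )

        term = assertion.go_id
        supporter_ids = [tree.leaves[s].subject for s in supporters]
        template = sample.get((supporters[0], term))
        aspect = template.aspect if template is not None else "P"
        qualifiers = list(template.qualifiers) if template is not None else []

        result.ibd_records.append(
            Annotation(
                db=ANCESTOR_DB,
                db_object_id=node,
                db_object_symbol=node,
                qualifiers=qualifiers,
                go_id=term,
                references=[load_reference],
                evidence_code="IBD",
                with_from=supporter_ids,
                aspect=aspect,
                db_object_type="ancestral_node",
                taxon=["taxon:1"],
                date=run_date,
                assigned_by=assigned_by,
            )
        )

        blocking_nodes = blocks_by_term.get(term, set())
        if node in blocking_nodes:
            logger.warning(
                "assertion node %s itself carries a block for %s; nothing propagates",
                node,
                term,
            )

        for leaf in tree.descendant_leaves(node):
            if term in positive.get(leaf, set()):
                continue  # already annotated experimentally to exactly this term
            path = tree.path(node, leaf)
            blocking = next((n for n in path if n in blocking_nodes), None)
            if blocking is not None:
                result.blocked_leaf_records.append(
                    (leaf, term, block_reason[(blocking, term)])
                )
                continue
            if term in notted.get(leaf, set()):
                result.blocked_leaf_records.append((leaf, term, "NOT"))
                continue
            identity = tree.leaves[leaf]
            result.iba_records.append(
                Annotation(
                    db=identity.db,
                    db_object_id=identity.gene_id,
                    db_object_symbol=identity.gene_id,
                    qualifiers=qualifiers,
                    go_id=term,
                    references=[load_reference],
                    evidence_code="IBA",
                    with_from=[node] + supporter_ids,
                    aspect=aspect,
                    db_object_type="gene",
                    taxon=[f"taxon:{identity.taxon_id}"],
                    date=run_date,
                    assigned_by=assigned_by,
                )
            )
    return result


def propose_mrca_assertions(
    tree: GeneTree,
    leaf_annotations: GafDocument,
    min_supporters: int = 2,
) -> list[NodeAssertion]:
    """Heuristic pre-curation aid: propose assertions at the MRCA of support.

    For every term held experimentally (without NOT) by at least
    ``min_supporters`` leaves, propose an assertion at the most recent
    common ancestor of those leaves. Proposals are never auto-applied:
    deciding which functions are truly ancestral is curation.
    """
    if min_supporters < 1:
        raise ValidationError("min_supporters must be >= 1")
    positive, _, _ = _experimental_by_leaf(tree, leaf_annotations)
    by_term: dict[str, list[str]] = {}
    order = {lab: i for i, lab in enumerate(tree.preorder)}
    for leaf, terms in positive.items():
        for term in terms:
            by_term.setdefault(term, []).append(leaf)
    proposals: list[NodeAssertion] = []
    for term in sorted(by_term):
        supporters = sorted(by_term[term], key=order.__getitem__)
        if len(supporters) < min_supporters:
            continue
        proposals.append(
            NodeAssertion(
                node_label=tree.mrca(supporters),
                go_id=term,
                supporting_leaves=supporters,
            )
        )
    return proposals
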