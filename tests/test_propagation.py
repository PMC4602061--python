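"""Gene-tree parsing and PAINT-style IBD/IBA propagation."""

import io

import pytest

import goannot
from goannot.errors import ParseError, ValidationError
from goannot.gaf_io import GafDocument
from goannot.propagation import (
    NodeAssertion,
    PropagationBlock,
    propagate,
    propose_mrca_assertions,
    read_tree,
)

from oracles import parse_newick_parent_map, propagation_oracle

A, B = "10090|MGI:A", "10090|MGI:B"
C, D = "9606|UniProtKB:C", "9606|UniProtKB:D"
FOUR_LEAF = f"(('{A}','{B}')X,('{C}','{D}')Y)R;"
TERM = "GO:0000010"


def leaf_ann(label, go_id=TERM, evidence="IDA", qualifiers=()):
    taxon, rest = label.split("|", 1)
    db, gene = rest.split(":", 1)
    return goannot.Annotation(
        db=db,
        db_object_id=gene,
        db_object_symbol=gene,
        qualifiers=list(qualifiers),
        go_id=go_id,
        references=["PMID:1"],
        evidence_code=evidence,
        with_from=[],
        aspect="F",
        taxon=[f"taxon:{taxon}"],
        date="20150601",
        assigned_by="test",
    )


def doc(*annotations):
    return GafDocument(version="2.2", header_lines=["!gaf-version: 2.2"], annotations=list(annotations))


def test_two_leaf_tree_parses():
    tree = read_tree(f"('{A}','{B}')R;")
    assert tree.root == "R"
    assert set(tree.leaves) == {A, B}
    assert tree.leaves[A].taxon_id == 10090
    assert tree.leaves[A].gene_id == "A"


def test_unlabeled_internal_nodes_autolabeled_preorder():
    tree = read_tree(f"(('{A}','{B}'),('{C}','{D}'));")
    internal = [n for n in tree.preorder if n not in tree.leaves]
    assert internal == ["ANC1", "ANC2", "ANC3"]
    assert tree.parent[A] == "ANC2"
    assert tree.parent[C] == "ANC3"


def test_duplicate_labels_rejected():
    with pytest.raises(ParseError, match="duplicate"):
        read_tree(f"('{A}','{A}')R;")


def test_unparseable_newick_rejected():
    with pytest.raises(ParseError):
        read_tree("((A,B;")


def test_fixture_tree_matches_second_parser(bundle, tree):
    parent, leaves, root = parse_newick_parent_map(bundle.newick)
    assert set(tree.leaves) == leaves
    assert tree.root == root
    assert tree.parent == parent


def test_worked_four_leaf_example():
    """A,B experimental; assertion at R; D blocked -> one IBA (C), one IBD."""
    tree = read_tree(FOUR_LEAF)
    annotations = doc(leaf_ann(A), leaf_ann(B))
    assertion = NodeAssertion("R", TERM, [A, B])
    block = PropagationBlock(D, TERM, "IKR")
    result = propagate(tree, annotations, [assertion], [block], run_date="20150601")
    assert len(result.ibd_records) == 1
    ibd = result.ibd_records[0]
    assert ibd.db_object_id == "R" and ibd.evidence_code == "IBD"
    assert ibd.with_from == ["MGI:A", "MGI:B"]
    assert len(result.iba_records) == 1
    iba = result.iba_records[0]
    assert (iba.db, iba.db_object_id) == ("UniProtKB", "C")
    assert iba.evidence_code == "IBA"
    assert iba.with_from == ["R", "MGI:A", "MGI:B"]
    assert result.blocked_leaf_records == [(D, TERM, "IKR")]


def test_no_assertions_empty_result(tree, docs):
    annotations = GafDocument(annotations=[a for d in docs.values() for a in d])
    result = propagate(tree, annotations, [], [])
    assert not result.ibd_records and not result.iba_records


def test_experimental_not_acts_as_leaf_block():
    tree = read_tree(FOUR_LEAF)
    annotations = doc(leaf_ann(A), leaf_ann(B), leaf_ann(C, qualifiers=["NOT", "enables"]))
    result = propagate(tree, annotations, [NodeAssertion("R", TERM, [A, B])], run_date="20150601")
    # A, B hold the term experimentally; C is NOT-blocked; only D gets IBA
    assert [r.db_object_id for r in result.iba_records] == ["D"]
    assert (C, TERM, "NOT") in result.blocked_leaf_records


def test_assertion_node_must_be_ancestral():
    tree = read_tree(FOUR_LEAF)
    with pytest.raises(ValidationError, match="not ancestral"):
        propagate(tree, doc(leaf_ann(A)), [NodeAssertion("X", TERM, [C])])


def test_block_outside_tree_rejected(tree):
    with pytest.raises(ValidationError, match="unknown node"):
        propagate(tree, doc(), [], [PropagationBlock("NOPE", TERM, "IRD")])


def fixture_propagation(bundle, tree, docs, assertions, blocks):
    annotations = GafDocument(annotations=[a for d in docs.values() for a in d])
    return propagate(tree, annotations, assertions, blocks, run_date="20150601")


def test_fixture_iba_matches_path_walk_oracle(bundle, tree, docs, assertions, blocks):
    result = fixture_propagation(bundle, tree, docs, assertions, blocks)
    parent, leaves, _ = parse_newick_parent_map(bundle.newick)
    exp, notted = {}, {}
    for d in docs.values():
        for ann in d.annotations:
            if goannot.classify_evidence(ann.evidence_code).method_class != "experimental":
                continue
            for label, ident in tree.leaves.items():
                if ident.subject == ann.subject:
                    (notted if ann.is_not else exp).setdefault(label, set()).add(ann.go_id)
    oracle = propagation_oracle(
        parent,
        leaves,
        exp,
        notted,
        [(a.node_label, a.go_id) for a in assertions],
        {(b.node_label, b.go_id) for b in blocks},
    )
    mine: dict[tuple, set] = {}
    for a in assertions:
        mine[(a.node_label, a.go_id)] = set()
    for rec in result.iba_records:
        node = rec.with_from[0]
        label = next(
            lab for lab, ident in tree.leaves.items() if ident.subject == rec.subject
        )
        mine[(node, rec.go_id)].add(label)
    assert mine == oracle


def test_conservation_per_assertion(bundle, tree, docs, assertions, blocks):
    result = fixture_propagation(bundle, tree, docs, assertions, blocks)
    annotations = GafDocument(annotations=[a for d in docs.values() for a in d])
    exp_by_leaf: dict[str, set] = {}
    for ann in annotations.annotations:
        if goannot.classify_evidence(ann.evidence_code).method_class != "experimental":
            continue
        if ann.is_not:
            continue
        for label, ident in tree.leaves.items():
            if ident.subject == ann.subject:
                exp_by_leaf.setdefault(label, set()).add(ann.go_id)
    iba_by_assert: dict[tuple, int] = {}
    for rec in result.iba_records:
        iba_by_assert[(rec.with_from[0], rec.go_id)] = (
            iba_by_assert.get((rec.with_from[0], rec.go_id), 0) + 1
        )
    blocked_by_term: dict[str, int] = {}
    for _, term, _ in result.blocked_leaf_records:
        blocked_by_term[term] = blocked_by_term.get(term, 0) + 1
    for assertion in assertions:
        descendants = tree.descendant_leaves(assertion.node_label)
        n_exp = sum(1 for l in descendants if assertion.go_id in exp_by_leaf.get(l, set()))
        n_iba = iba_by_assert.get((assertion.node_label, assertion.go_id), 0)
        n_blocked = sum(
            1
            for leaf, term, _ in result.blocked_leaf_records
            if term == assertion.go_id and leaf in descendants
        )
        assert n_iba + n_exp + n_blocked == len(descendants)


def test_ibd_count_equals_assertion_count(bundle, tree, docs, assertions, blocks):
    result = fixture_propagation(bundle, tree, docs, assertions, blocks)
    assert len(result.ibd_records) == len(assertions)


def test_blocks_only_shrink_iba(bundle, tree, docs, assertions, blocks):
    with_blocks = fixture_propagation(bundle, tree, docs, assertions, blocks)
    without = fixture_propagation(bundle, tree, docs, assertions, [])
    assert len(with_blocks.iba_records) <= len(without.iba_records)


def test_mrca_proposals():
    tree = read_tree(FOUR_LEAF)
    annotations = doc(leaf_ann(A), leaf_ann(D))
    proposals = propose_mrca_assertions(tree, annotations, min_supporters=2)
    assert len(proposals) == 1
    assert proposals[0].node_label == "R"
    assert proposals[0].supporting_leaves == [A, D]
    assert propose_mrca_assertions(tree, doc(leaf_ann(A)), min_supporters=2) == []


def test_mrca_matches_dendropy_oracle(bundle, tree, docs):
    import dendropy

    annotations = GafDocument(annotations=[a for d in docs.values() for a in d])
    proposals = propose_mrca_assertions(tree, annotations, min_supporters=2)
    assert proposals
    dtree = dendropy.Tree.get(
        data=bundle.newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=False,
    )
    dtree.is_rooted = True
    dtree.encode_bipartitions()
    for prop in proposals:
        taxa = [t for t in dtree.taxon_namespace if t.label in prop.supporting_leaves]
        node = dtree.mrca(taxa=taxa)
        label = node.label or (node.taxon.label if node.taxon else None)
        assert label == prop.node_label
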