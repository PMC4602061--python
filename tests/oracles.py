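"""Independent brute-force oracles for cross-checking the implementation.

Everything here is written against the raw file texts with plain loops
and string splitting — deliberately sharing no code with the package —
so that agreement between an oracle and the implementation is evidence,
not tautology.
"""

from __future__ import annotations

from collections import Counter

EXPERIMENTAL = {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"}


def parse_gaf_rows(text: str) -> list[list[str]]:
    rows = []
    for line in text.splitlines():
        if line.startswith("!") or not line.strip():
            continue
        rows.append(line.split("\t"))
    return rows


def parse_homologene_rows(text: str) -> dict[str, list[tuple[int, str]]]:
    classes: dict[str, list[tuple[int, str]]] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        cols = line.split("\t")
        classes.setdefault(cols[0], []).append((int(cols[1]), cols[2]))
    return classes


def transfer_oracle(
    source_gaf: str,
    target_gaf: str,
    homologene: str,
    source_taxon: int,
    target_taxon: int,
    load_reference: str,
    assigned_by: str,
    target_db: str,
    run_date: str,
    protein_binding_term: str = "GO:0005515",
    suppress_duplicates: bool = True,
    m2m_full_class: bool = True,
) -> tuple[set[tuple], Counter]:
    """Rule-by-rule re-implementation of the ISO transfer cascade.

    Returns the set of produced record tuples and the per-reason counts.
    """
    classes = parse_homologene_rows(homologene)
    class_of: dict[tuple[int, str], str] = {}
    for cid, members in classes.items():
        for taxon, gene in members:
            class_of[(taxon, gene)] = cid

    source_rows = parse_gaf_rows(source_gaf)
    target_rows = parse_gaf_rows(target_gaf)

    def taxon_of(row: list[str]) -> int:
        return int(row[12].split("|")[0].split(":")[1])

    def is_not(row: list[str]) -> bool:
        quals = row[3].split("|") if row[3] else []
        return bool(quals) and quals[0] == "NOT"

    # class-wide NOT blocks over source + target, any evidence class
    blocked: dict[str, set[str]] = {}
    for row in source_rows + target_rows:
        if not is_not(row):
            continue
        cid = class_of.get((taxon_of(row), row[1]))
        if cid is not None:
            blocked.setdefault(cid, set()).add(row[4])

    target_experimental = {
        (row[1], row[4])
        for row in target_rows
        if row[6] in EXPERIMENTAL and not is_not(row)
    }

    reasons: Counter = Counter()
    produced: set[tuple] = set()
    for row in source_rows:
        if row[6] not in EXPERIMENTAL:
            reasons["not_experimental"] += 1
            continue
        if is_not(row):
            reasons["not_qualifier"] += 1
            continue
        if row[4] == protein_binding_term:
            reasons["protein_binding"] += 1
            continue
        cid = class_of.get((source_taxon, row[1]))
        if cid is None:
            reasons["no_orthology_class"] += 1
            continue
        members = classes[cid]
        targets = [g for t, g in members if t == target_taxon]
        if not targets:
            reasons["no_target_partner"] += 1
            continue
        counted = (
            [t for t, _ in members]
            if m2m_full_class
            else [t for t, _ in members if t in (source_taxon, target_taxon)]
        )
        many_to_many = any(n >= 2 for n in Counter(counted).values())
        if row[8] == "P" and many_to_many:
            reasons["bp_in_many_to_many"] += 1
            continue
        if row[4] in blocked.get(cid, set()):
            reasons["class_not_blocked_but_term_notted"] += 1
            continue
        survivors = [
            g
            for g in targets
            if not (suppress_duplicates and (g, row[4]) in target_experimental)
        ]
        if not survivors:
            reasons["duplicate_of_experimental"] += 1
            continue
        reasons["ok"] += 1
        for gene in survivors:
            produced.add(
                (
                    target_db,
                    gene,
                    row[3],
                    row[4],
                    load_reference,
                    "ISO",
                    f"{row[0]}:{row[1]}",
                    row[8],
                    f"taxon:{target_taxon}",
                    run_date,
                    assigned_by,
                )
            )
    return produced, reasons


def annotation_tuple(ann) -> tuple:
    """Project a produced Annotation onto the oracle's tuple shape."""
    return (
        ann.db,
        ann.db_object_id,
        "|".join(ann.qualifiers),
        ann.go_id,
        ann.references[0],
        ann.evidence_code,
        ann.with_from[0],
        ann.aspect,
        ann.taxon[0],
        ann.date,
        ann.assigned_by,
    )


def parse_newick_parent_map(text: str) -> tuple[dict[str, str], set[str], str]:
    """Second, independent Newick parse via Bio.Phylo.

    Returns (parent map, leaf labels, root label); unlabeled internal
    nodes get ANC<n> in preorder, matching the documented auto-label rule.
    """
    import io as _io

    from Bio import Phylo

    tree = Phylo.read(_io.StringIO(text), "newick")
    parent: dict[str, str] = {}
    leaves: set[str] = set()
    counter = 0
    labels: dict[int, str] = {}
    root_label = None
    for clade in tree.find_clades(order="preorder"):
        name = clade.name
        if clade.is_terminal():
            leaves.add(name)
        elif not name:
            counter += 1
            name = f"ANC{counter}"
        labels[id(clade)] = name
        if root_label is None:
            root_label = name
    for clade in tree.find_clades(order="preorder"):
        for child in clade.clades:
            parent[labels[id(child)]] = labels[id(clade)]
    return parent, leaves, root_label


def propagation_oracle(
    parent: dict[str, str],
    leaves: set[str],
    exp_terms_by_leaf: dict[str, set[str]],
    not_terms_by_leaf: dict[str, set[str]],
    assertions: list[tuple[str, str]],
    blocks: set[tuple[str, str]],
) -> dict[tuple[str, str], set[str]]:
    """Path-walk propagation: IBA leaf set per (node, term) assertion."""

    def lineage(node: str) -> list[str]:
        chain = [node]
        while node in parent:
            node = parent[node]
            chain.append(node)
        return chain

    result: dict[tuple[str, str], set[str]] = {}
    for node, term in assertions:
        iba: set[str] = set()
        for leaf in leaves:
            line = lineage(leaf)
            if node not in line:
                continue
            path = line[: line.index(node) + 1]
            if term in exp_terms_by_leaf.get(leaf, set()):
                continue
            if any((n, term) in blocks for n in path):
                continue
            if term in not_terms_by_leaf.get(leaf, set()):
                continue
            iba.add(leaf)
        result[(node, term)] = iba
    return result


def slim_cover_oracle(term: str, slim: set[str], parents_closure: dict[str, set[str]]) -> set[str]:
    """Enumerate covering slim terms, then drop dominated (less specific) ones."""
    covering = {s for s in slim if s == term or s in parents_closure.get(term, set())}
    return {
        s
        for s in covering
        if not any(o != s and s in parents_closure.get(o, set()) for o in covering)
    }


def bfs_ancestors(term: str, edges: dict[str, set[str]]) -> set[str]:
    """Breadth-first ancestor closure over an explicit edge map."""
    out: set[str] = set()
    frontier = [term]
    while frontier:
        nxt = []
        for node in frontier:
            for p in edges.get(node, set()):
                if p not in out:
                    out.add(p)
                    nxt.append(p)
        frontier = nxt
    return out
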