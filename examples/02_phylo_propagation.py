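"""PAINT-style propagation on a 4-leaf gene tree.

Mouse genes A and B hold a term experimentally; a curator asserts the
function is ancestral at the root and blocks one diverged human gene.
The run emits one IBD record (the ancestral assertion) and IBA records
for the uncharacterized leaves that are not blocked.
"""

import goannot
from goannot.propagation import NodeAssertion, PropagationBlock

A, B = "10090|MGI:A", "10090|MGI:B"
C, D = "9606|UniProtKB:C", "9606|UniProtKB:D"
tree = goannot.read_tree(f"(('{A}','{B}')X,('{C}','{D}')Y)R;")

TERM = "GO:0000010"


def experimental(label):
    taxon, rest = label.split("|", 1)
    db, gene = rest.split(":", 1)
    return goannot.Annotation(
        db=db, db_object_id=gene, db_object_symbol=gene, qualifiers=[],
        go_id=TERM, references=["PMID:1"], evidence_code="IDA", with_from=[],
        aspect="F", taxon=[f"taxon:{taxon}"], date="20150601", assigned_by="example",
    )


leaf_annotations = goannot.GafDocument(annotations=[experimental(A), experimental(B)])
result = goannot.propagate(
    tree,
    leaf_annotations,
    assertions=[NodeAssertion("R", TERM, [A, B])],
    blocks=[PropagationBlock(D, TERM, "IKR")],  # function lost in D's branch
    run_date="20150601",
)

print(f"IBD records: {len(result.ibd_records)}  (one per ancestral assertion)")
ibd = result.ibd_records[0]
print(f"  node {ibd.db_object_id} {ibd.go_id} supporters={ibd.with_from}")
print(f"IBA records: {len(result.iba_records)}  (propagated to eligible leaves)")
for r in result.iba_records:
    print(f"  {r.db}:{r.db_object_id} {r.go_id} via {r.with_from[0]}")
print(f"blocked: {result.blocked_leaf_records}")
# A and B are skipped (already experimental); D is blocked (IKR); only C
# inherits the ancestral function as an IBA annotation.
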