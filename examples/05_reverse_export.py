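"""Reverse export: curated mouse ISO records become experimental records
of the orthologous non-mouse gene, citing the original publication."""

import goannot
from goannot.transfer import reverse_export

curated = goannot.GafDocument(
    annotations=[
        goannot.Annotation(
            db="MGI", db_object_id="MGI:1344411", db_object_symbol="Celf4",
            qualifiers=["enables"], go_id="GO:0000010",
            references=["GO_REF:0000008"],  # marks the record as orthology-curated
            evidence_code="ISO", with_from=["UniProtKB:Q9BZC1"], aspect="F",
            taxon=["taxon:10090"], date="20140101", assigned_by="MGI",
        )
    ]
)
# the curator read this publication when asserting conservation:
evidence_map = {("MGI", "MGI:1344411", "GO:0000010"): ("IDA", "PMID:11158314")}
taxon_map = {"UniProtKB:Q9BZC1": 9606}

exported = reverse_export(curated, evidence_map, taxon_map)
rec = exported.annotations[0]
print(f"curated subject : MGI:MGI:1344411 (mouse Celf4, ISO via {curated.annotations[0].with_from[0]})")
print(f"exported subject: {rec.db}:{rec.db_object_id} taxon={rec.taxon[0]}")
print(f"evidence        : {rec.evidence_code} ref={rec.references[0]}")
# The with/from human gene becomes the annotated subject, carrying the
# experimental evidence code and publication instead of the orthology load
# reference — the form shared back with the human annotation resource.
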