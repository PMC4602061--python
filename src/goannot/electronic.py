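"""Mapping-file-driven electronic (IEA) annotation.

External classification systems — Enzyme Commission numbers, Swiss-Prot
keywords, InterPro domains — are curated against GO in "external2go"
mapping files. Given such a mapping and a table stating which external
identifiers each gene carries, this module emits IEA ("inferred from
electronic annotation") records. One generic engine serves all three
pipelines; the pipeline identity lives in the load reference and in the
with/from external identifier.

The external2go line dialect is::

    <NS>:<id> <name> > GO:<term name> ; GO:nnnnnnn

with ``!`` comment lines; a line may chain several ``> ... ; GO:...``
mappings, producing one rule each.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from datetime import date as _date
from typing import IO, Iterable, Sequence

from goannot.errors import ParseError
from goannot.gaf_io import Annotation, GafDocument, dedupe
from goannot.ontology import Ontology

logger = logging.getLogger(__name__)

_GO_ACC_RE = re.compile(r"GO:\d{7}")


@dataclass(frozen=True)
class MappingRule:
    external_id: str
    external_name: str
    go_id: str


@dataclass(frozen=True)
class GeneFeature:
    """One row of the feature table: a gene carries an external identifier."""

    db: str
    gene_id: str
    symbol: str
    taxon: int
    external_id: str


def read_mapping2go(stream: IO[str]) -> list[MappingRule]:
    """Parse an external2go mapping file into rules."""
    rules: list[MappingRule] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!"):
            continue
        if " > " not in line:
            raise ParseError("mapping line lacks ' > ' separator", line=lineno)
        head, _, tail = line.partition(" > ")
        head = head.strip()
        if ":" not in head:
            raise ParseError(f"external id {head.split()[0]!r} lacks a namespace", line=lineno)
        external_id, _, external_name = head.partition(" ")
        accessions = _GO_ACC_RE.findall(tail)
        # term names may themselves start with "GO:<name>"; accessions are
        # the 7-digit forms, which the name part never matches
        if not accessions:
            raise ParseError("mapping line lacks a terminal GO accession", line=lineno)
        for acc in accessions:
            rules.append(
                MappingRule(
                    external_id=external_id,
                    external_name=external_name.strip(),
                    go_id=acc,
                )
            )
    return rules


def read_features(stream: IO[str]) -> list[GeneFeature]:
    """Feature TSV: db <tab> gene_id <tab> symbol <tab> taxon <tab> external_id."""
    out: list[GeneFeature] = []
    reader = csv.reader(stream, delimiter="\t")
    for lineno, cols in enumerate(reader, start=1):
        if not cols or (cols[0].startswith("#")):
            continue
        if len(cols) != 5:
            raise ParseError(f"expected 5 columns, got {len(cols)}", line=lineno)
        try:
            taxon = int(cols[3])
        except ValueError:
            raise ParseError(f"non-integer taxon {cols[3]!r}", line=lineno) from None
        out.append(GeneFeature(cols[0], cols[1], cols[2], taxon, cols[4]))
    return out


def generate_iea(
    gene_features: Sequence[GeneFeature],
    rules: Iterable[MappingRule],
    load_reference: str,
    assigned_by: str,
    ontology: Ontology,
    run_date: str | None = None,
) -> GafDocument:
    """Join features against mapping rules and emit deduped IEA records.

    Rules whose GO term is absent from the ontology are dropped with a
    warning; obsolete terms are dropped with a logged count. The join is
    deterministic and idempotent given fixed inputs and date.
    """
    run_date = run_date or _date.today().strftime("%Y%m%d")
    by_external: dict[str, list[MappingRule]] = {}
    for rule in rules:
        by_external.setdefault(rule.external_id, []).append(rule)

    records: list[Annotation] = []
    dropped_unknown = 0
    dropped_obsolete = 0
    for feat in gene_features:
        for rule in by_external.get(feat.external_id, []):
            if rule.go_id not in ontology:
                dropped_unknown += 1
                logger.warning(
                    "mapping %s -> %s: term not in ontology; record dropped",
                    rule.external_id,
                    rule.go_id,
                )
                continue
            term = ontology.term(rule.go_id)
            if term.obsolete:
                dropped_obsolete += 1
                continue
            records.append(
                Annotation(
                    db=feat.db,
                    db_object_id=feat.gene_id,
                    db_object_symbol=feat.symbol or feat.gene_id,
                    qualifiers=[],
                    go_id=term.id,
                    references=[load_reference],
                    evidence_code="IEA",
                    with_from=[feat.external_id],
                    aspect=ontology.aspect_of(term.id),
                    db_object_type="gene",
                    taxon=[f"taxon:{feat.taxon}"],
                    date=run_date,
                    assigned_by=assigned_by,
                )
            )
    if dropped_obsolete:
        logger.info("dropped %d mappings to obsolete terms", dropped_obsolete)
    return GafDocument(
        version="2.2",
        header_lines=["!gaf-version: 2.2", "!generated-by: goannot iea"],
        annotations=dedupe(records),
    )
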