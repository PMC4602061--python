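"""Orthology-based annotation transfer (ISO) and its reverse export.

The forward direction turns experimental annotations of a source species
(e.g. human or rat) into ISO ("inferred from sequence orthology") records
for the orthologous genes of a target species (e.g. mouse). Eligibility is
a fixed-order rule cascade; the first failing rule decides the rejection
reason, which makes reports deterministic:

1.  only *experimental* evidence transfers — inferred evidence (ISO, IBA,
    IEA, ...) is never re-transferred, which prevents circular annotation
    between resources;
2.  NOT-qualified records never transfer — an experimentally demonstrated
    absence of function cannot be reliably inferred across species;
3.  protein binding (GO:0005515) never transfers — such annotations
    describe a specific binding event, not a conserved property;
4.  the source gene must belong to an orthology class;
5.  the class must contain at least one target-species gene;
6.  in a many-to-many class (some species contributes two or more genes)
    only molecular-function and cellular-component annotations transfer —
    biological-process records are rejected;
7.  a term is blocked class-wide when *any* class member, in any species,
    carries a NOT annotation to it;
8.  optionally, target genes that already hold the same term with
    experimental evidence are skipped.

The reverse direction (:func:`reverse_export`) converts curated
orthology-evidence records (ISO/ISA/ISS with a with/from gene) into
experimental annotations *of the with/from gene*, citing the original
publication — the form in which such curation is shared back with the
source species' annotation resource.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Iterable, Mapping, Sequence

from goannot.errors import UsageError
from goannot.gaf_io import (
    Annotation,
    GafDocument,
    classify_evidence,
    dedupe,
)
from goannot.ontology import Ontology
from goannot.orthology import OrthologyClass, OrthologySet, is_many_to_many

logger = logging.getLogger(__name__)

#: rejection reasons, in rule order; "ok" marks acceptance.
REASONS = (
    "ok",
    "not_experimental",
    "not_qualifier",
    "protein_binding",
    "no_orthology_class",
    "no_target_partner",
    "bp_in_many_to_many",
    "class_not_blocked_but_term_notted",
    "duplicate_of_experimental",
)

REVERSIBLE_EVIDENCE = frozenset({"ISO", "ISA", "ISS"})


@dataclass
class TransferConfig:
    """Parameters of one transfer load.

    Each load carries a dedicated reference accession
    (``load_reference``, e.g. a GO_REF) and names the transferring
    resource as ``assigned_by``, since the orthology assertion — not the
    original experiment — is the basis of the new record.
    """

    source_taxon: int
    target_taxon: int
    load_reference: str
    assigned_by: str
    target_db: str = "MGI"
    protein_binding_term: str = "GO:0005515"
    suppress_if_experimental_duplicate: bool = True
    many_to_many_scope: str = "full_class"  # or "species_pair"
    block_descendant_terms: bool = False  # NOT blocking via ontology closure

    def __post_init__(self) -> None:
        if self.source_taxon == self.target_taxon:
            raise UsageError("source_taxon and target_taxon must differ")
        if self.many_to_many_scope not in {"full_class", "species_pair"}:
            raise UsageError(f"unknown many_to_many_scope {self.many_to_many_scope!r}")


@dataclass
class TransferDecision:
    source_annotation: Annotation
    outcome: str  # accepted | rejected
    reason: str  # member of REASONS
    produced: list[Annotation] = field(default_factory=list)


@dataclass
class TransferReport:
    reason_counts: Counter = field(default_factory=Counter)
    produced_per_gene: Counter = field(default_factory=Counter)
    evaluated: int = 0
    accepted: int = 0
    produced_total: int = 0  # after dedupe

    def add(self, decision: TransferDecision) -> None:
        self.evaluated += 1
        self.reason_counts[decision.reason] += 1
        if decision.outcome == "accepted":
            self.accepted += 1
            for ann in decision.produced:
                self.produced_per_gene[ann.db_object_id] += 1


def _annotation_taxon(ann: Annotation) -> int | None:
    if not ann.taxon:
        return None
    token = ann.taxon[0]
    try:
        return int(token.split(":", 1)[1])
    except (IndexError, ValueError):
        return None


def blocked_terms(
    cls: OrthologyClass,
    all_annotations: Iterable[Annotation],
    ontology: Ontology | None = None,
    block_descendants: bool = False,
) -> set[str]:
    """Terms blocked class-wide by a NOT annotation on any class member.

    Any member of the class, in any species and under any evidence class,
    carrying a NOT annotation to a term blocks transfer of that term to
    every member. Matching is exact-term by default; with
    ``block_descendants`` the block extends to descendant terms via
    is_a/part_of closure (requires an ontology).
    """
    members = {(m.taxon_id, m.gene_id) for m in cls.members}
    notted: set[str] = set()
    for ann in all_annotations:
        if not ann.is_not:
            continue
        taxon = _annotation_taxon(ann)
        if taxon is not None and (taxon, ann.db_object_id) in members:
            notted.add(ann.go_id)
    if block_descendants and ontology is not None:
        blocked = set(notted)
        for term in ontology.terms.values():
            if term.obsolete:
                continue
            if notted & ontology.ancestors(term.id):
                blocked.add(term.id)
        return blocked
    return notted


def _experimental_index(annotations: Iterable[Annotation]) -> set[tuple[str, str]]:
    """(gene_id, go_id) pairs held experimentally without NOT."""
    index: set[tuple[str, str]] = set()
    for ann in annotations:
        if ann.is_not:
            continue
        if classify_evidence(ann.evidence_code).method_class == "experimental":
            index.add((ann.db_object_id, ann.go_id))
    return index


def evaluate(
    annotation: Annotation,
    ortho: OrthologySet,
    ontology: Ontology,
    config: TransferConfig,
    target_annotations: Sequence[Annotation] = (),
    blocked: Mapping[str, set[str]] | None = None,
    run_date: str | None = None,
    _target_experimental: set[tuple[str, str]] | None = None,
) -> TransferDecision:
    """Apply the transfer rule cascade to one source annotation.

    Rules fire in the fixed order documented in the module docstring; the
    first failure is the recorded reason. The evidence-class rule fires
    before the source-taxon guard, so feeding a pipeline's own inferred
    output back in is rejected as ``not_experimental`` rather than being
    an error — the guard protects only experimental records from being
    evaluated under the wrong configuration.
    """
    run_date = run_date or _date.today().strftime("%Y%m%d")

    def reject(reason: str) -> TransferDecision:
        return TransferDecision(annotation, outcome="rejected", reason=reason)

    # (1) experimental evidence only — prevents circular annotation
    if classify_evidence(annotation.evidence_code).method_class != "experimental":
        return reject("not_experimental")

    taxon = _annotation_taxon(annotation)
    if taxon != config.source_taxon:
        raise UsageError(
            f"annotation taxon {annotation.taxon} does not match configured "
            f"source taxon {config.source_taxon}"
        )

    # (2) NOT never transfers across species
    if annotation.is_not:
        return reject("not_qualifier")

    # (3) protein binding is event-specific, never transferred
    if annotation.go_id == config.protein_binding_term:
        return reject("protein_binding")

    # (4) the source gene must be classified
    cls = ortho.class_of(config.source_taxon, annotation.db_object_id)
    if cls is None:
        return reject("no_orthology_class")

    # (5) and its class must reach the target species
    targets = cls.genes_of(config.target_taxon)
    if not targets:
        return reject("no_target_partner")

    # (6) BP does not transfer within many-to-many classes
    scope_taxa = (
        None
        if config.many_to_many_scope == "full_class"
        else (config.source_taxon, config.target_taxon)
    )
    if annotation.aspect == "P" and is_many_to_many(cls, scope_taxa):
        return reject("bp_in_many_to_many")

    # (7) class-wide NOT block on this term
    if blocked and annotation.go_id in blocked.get(cls.class_id, set()):
        return reject("class_not_blocked_but_term_notted")

    # (8) optional suppression against existing target experimental records
    if _target_experimental is None:
        _target_experimental = _experimental_index(target_annotations)
    survivors = [
        m
        for m in targets
        if not (
            config.suppress_if_experimental_duplicate
            and (m.gene_id, annotation.go_id) in _target_experimental
        )
    ]
    if not survivors:
        return reject("duplicate_of_experimental")

    produced = [
        Annotation(
            db=config.target_db,
            db_object_id=member.gene_id,
            db_object_symbol=member.symbol or member.gene_id,
            qualifiers=list(annotation.qualifiers),
            go_id=annotation.go_id,
            references=[config.load_reference],
            evidence_code="ISO",
            with_from=[annotation.subject],
            aspect=annotation.aspect,
            db_object_type=annotation.db_object_type or "gene",
            taxon=[f"taxon:{config.target_taxon}"],
            date=run_date,
            assigned_by=config.assigned_by,
        )
        for member in survivors
    ]
    return TransferDecision(annotation, outcome="accepted", reason="ok", produced=produced)


def run_transfer(
    source_doc: GafDocument,
    target_doc: GafDocument,
    ortho: OrthologySet,
    ontology: Ontology,
    config: TransferConfig,
    run_date: str | None = None,
) -> tuple[GafDocument, TransferReport, list[TransferDecision]]:
    """Evaluate every source record and collect the produced ISO document.

    Class-wide NOT blocks are derived from the union of the source and
    target documents (any member, any species, any evidence class). The
    produced document is deduped on the annotation identity key. Output is
    deterministic given the inputs and the run date.
    """
    run_date = run_date or _date.today().strftime("%Y%m%d")
    pool = list(source_doc.annotations) + list(target_doc.annotations)
    blocked: dict[str, set[str]] = {
        cid: blocked_terms(
            cls, pool, ontology=ontology, block_descendants=config.block_descendant_terms
        )
        for cid, cls in ortho.classes.items()
    }
    target_experimental = _experimental_index(target_doc.annotations)

    report = TransferReport()
    decisions: list[TransferDecision] = []
    produced: list[Annotation] = []
    for ann in source_doc.annotations:
        decision = evaluate(
            ann,
            ortho,
            ontology,
            config,
            blocked=blocked,
            run_date=run_date,
            _target_experimental=target_experimental,
        )
        decisions.append(decision)
        report.add(decision)
        produced.extend(decision.produced)

    unique = dedupe(produced)
    report.produced_total = len(unique)
    out = GafDocument(
        version="2.2",
        header_lines=[
            "!gaf-version: 2.2",
            f"!generated-by: goannot transfer {config.source_taxon}->{config.target_taxon}",
        ],
        annotations=unique,
    )
    return out, report, decisions


def reverse_export(
    curated: GafDocument,
    evidence_map: Mapping[tuple[str, str, str], tuple[str, str]],
    taxon_map: Mapping[str, int],
    config: TransferConfig | None = None,
) -> GafDocument:
    """Convert curated ISO/ISA/ISS records into annotations of their with/from gene.

    ``evidence_map`` maps the curated record's key ``(db, db_object_id,
    go_id)`` to ``(experimental evidence code, publication reference)`` —
    the experiment the curator read when asserting conservation.
    ``taxon_map`` maps each with/from token (``DB:id``) to its NCBI taxon.
    Records with other evidence, absent from the map, or with a malformed
    with/from token are skipped with a logged count.
    """
    out: list[Annotation] = []
    skipped = Counter()
    for ann in curated.annotations:
        if ann.evidence_code not in REVERSIBLE_EVIDENCE:
            skipped["ineligible_evidence"] += 1
            continue
        if not ann.with_from:
            skipped["no_with_from"] += 1
            continue
        key = (ann.db, ann.db_object_id, ann.go_id)
        mapped = evidence_map.get(key)
        if mapped is None:
            skipped["no_evidence_mapping"] += 1
            continue
        evidence_code, reference = mapped
        token = ann.with_from[0]
        if ":" not in token:
            logger.warning("with/from token %r lacks a DB: prefix; record skipped", token)
            skipped["bad_with_from"] += 1
            continue
        subj_db, subj_id = token.split(":", 1)
        taxon = taxon_map.get(token)
        if taxon is None:
            logger.warning("no taxon mapping for with/from token %r; record skipped", token)
            skipped["no_taxon_mapping"] += 1
            continue
        out.append(
            Annotation(
                db=subj_db,
                db_object_id=subj_id,
                db_object_symbol=subj_id,
                qualifiers=list(ann.qualifiers),
                go_id=ann.go_id,
                references=[reference],
                evidence_code=evidence_code,
                with_from=[],
                aspect=ann.aspect,
                db_object_type=ann.db_object_type or "gene",
                taxon=[f"taxon:{taxon}"],
                date=ann.date,
                assigned_by=ann.assigned_by,
            )
        )
    if skipped:
        logger.info("reverse export skipped records: %s", dict(skipped))
    return GafDocument(
        version=curated.version,
        header_lines=["!gaf-version: " + curated.version, "!generated-by: goannot reverse-export"],
        annotations=out,
    )
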