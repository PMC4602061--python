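"""GAF 2.1/2.2 and GPAD 1.1 annotation I/O, evidence-code classification.

GAF (Gene Association File) is the GO Consortium's 17-column tab-separated
exchange format; every annotation pipeline in this package consumes and
emits it. The reader/writer pair is bit-exact: ``read -> write -> read``
reproduces every field, so transformed files diff cleanly against their
inputs.

GPAD (Gene Product Association Data) separates annotation data from gene
object metadata; :func:`write_gpad` emits the annotation-only columns for
consumers that keep object metadata in a companion GPI file.

Evidence codes are the GO three-letter mnemonics. :func:`classify_evidence`
buckets them into the method classes used for summary reporting:
experimental (EXP/IDA/IPI/IMP/IGI/IEP), sequence-similarity
(ISS/ISO/ISA/ISM/IGC), phylogenetic (IBA/IBD/IKR/IRD), electronic (IEA),
and ``other`` for everything else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import IO, Iterable, Sequence

from goannot.errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

GAF_COLUMNS = 17
GPAD_COLUMNS = 12

EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})
SEQUENCE_SIMILARITY_CODES = frozenset({"ISS", "ISO", "ISA", "ISM", "IGC"})
PHYLOGENETIC_CODES = frozenset({"IBA", "IBD", "IKR", "IRD"})
ELECTRONIC_CODES = frozenset({"IEA"})

#: GAF 2.2 default gene-product-to-term relations by aspect, used when a
#: record written as GPAD carries no explicit relation qualifier.
DEFAULT_RELATION_BY_ASPECT = {"F": "enables", "P": "involved_in", "C": "located_in"}

MANDATORY_FIELDS = (
    "db",
    "db_object_id",
    "go_id",
    "evidence_code",
    "taxon",
    "date",
    "assigned_by",
)


@dataclass
class Annotation:
    """One GAF record.

    ``qualifiers`` is the ordered column-4 list; when ``NOT`` is present it
    is the first element (both the bare GAF 2.1 ``NOT`` and the GAF 2.2
    ``NOT|relation`` forms satisfy this). ``annotation_extension`` and
    ``gene_product_form_id`` (which houses isoform identifiers) are carried
    opaquely.
    """

    db: str
    db_object_id: str
    db_object_symbol: str
    qualifiers: list[str]
    go_id: str
    references: list[str]
    evidence_code: str
    with_from: list[str]
    aspect: str
    db_object_name: str = ""
    synonyms: list[str] = field(default_factory=list)
    db_object_type: str = "protein"
    taxon: list[str] = field(default_factory=list)
    date: str = ""
    assigned_by: str = ""
    annotation_extension: str = ""
    gene_product_form_id: str = ""

    @property
    def gene_key(self) -> tuple[str, str]:
        return (self.db, self.db_object_id)

    @property
    def subject(self) -> str:
        """The annotated object in ``DB:id`` form (the with/from token dialect)."""
        return f"{self.db}:{self.db_object_id}"

    @property
    def is_not(self) -> bool:
        return bool(self.qualifiers) and self.qualifiers[0] == "NOT"

    def copy(self, **changes) -> "Annotation":
        out = replace(self)
        # containers are mutable; never share them between copies
        out.qualifiers = list(self.qualifiers)
        out.references = list(self.references)
        out.with_from = list(self.with_from)
        out.synonyms = list(self.synonyms)
        out.taxon = list(self.taxon)
        for key, value in changes.items():
            setattr(out, key, value)
        return out


@dataclass(frozen=True)
class EvidenceClass:
    code: str
    method_class: str  # experimental | sequence_similarity | phylogenetic | electronic | other


@dataclass
class GafDocument:
    version: str = "2.2"
    header_lines: list[str] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)


def classify_evidence(code: str) -> EvidenceClass:
    """Total classification of an evidence code into its method class."""
    if code in EXPERIMENTAL_CODES:
        cls = "experimental"
    elif code in SEQUENCE_SIMILARITY_CODES:
        cls = "sequence_similarity"
    elif code in PHYLOGENETIC_CODES:
        cls = "phylogenetic"
    elif code in ELECTRONIC_CODES:
        cls = "electronic"
    else:
        cls = "other"
    return EvidenceClass(code=code, method_class=cls)


def _split(value: str) -> list[str]:
    return value.split("|") if value else []


def read_gaf(stream: IO[str]) -> GafDocument:
    """Parse a GAF 2.1 or 2.2 stream.

    The first line must declare ``!gaf-version: 2.1`` or ``2.2``. Records
    with a wrong column count raise :class:`ParseError` with the line
    number; an unparseable date only logs a warning and the record keeps
    its raw date text (round trips stay exact).
    """
    version: str | None = None
    header_lines: list[str] = []
    annotations: list[Annotation] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if lineno == 1:
            if not line.startswith("!gaf-version:"):
                raise ParseError("missing !gaf-version header", line=lineno)
            version = line.split(":", 1)[1].strip()
            if version not in {"2.1", "2.2"}:
                raise ParseError(f"unsupported gaf-version {version!r}", line=lineno)
            header_lines.append(line)
            continue
        if line.startswith("!"):
            header_lines.append(line)
            continue
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != GAF_COLUMNS:
            raise ParseError(
                f"expected {GAF_COLUMNS} tab-separated columns, got {len(cols)}",
                line=lineno,
            )
        ann = Annotation(
            db=cols[0],
            db_object_id=cols[1],
            db_object_symbol=cols[2],
            qualifiers=_split(cols[3]),
            go_id=cols[4],
            references=_split(cols[5]),
            evidence_code=cols[6],
            with_from=_split(cols[7]),
            aspect=cols[8],
            db_object_name=cols[9],
            synonyms=_split(cols[10]),
            db_object_type=cols[11],
            taxon=_split(cols[12]),
            date=cols[13],
            assigned_by=cols[14],
            annotation_extension=cols[15],
            gene_product_form_id=cols[16],
        )
        try:
            datetime.strptime(ann.date, "%Y%m%d")
        except ValueError:
            logger.warning("line %d: invalid date %r; record kept", lineno, ann.date)
        annotations.append(ann)
    if version is None:
        raise ParseError("empty stream: missing !gaf-version header")
    return GafDocument(version=version, header_lines=header_lines, annotations=annotations)


def _gaf_row(ann: Annotation) -> list[str]:
    return [
        ann.db,
        ann.db_object_id,
        ann.db_object_symbol,
        "|".join(ann.qualifiers),
        ann.go_id,
        "|".join(ann.references),
        ann.evidence_code,
        "|".join(ann.with_from),
        ann.aspect,
        ann.db_object_name,
        "|".join(ann.synonyms),
        ann.db_object_type,
        "|".join(ann.taxon),
        ann.date,
        ann.assigned_by,
        ann.annotation_extension,
        ann.gene_product_form_id,
    ]


def _check_mandatory(ann: Annotation, index: int) -> None:
    for name in MANDATORY_FIELDS:
        if not getattr(ann, name):
            raise ValidationError(
                f"record {index} ({ann.db}:{ann.db_object_id} -> {ann.go_id!r}): "
                f"mandatory column {name!r} is empty"
            )


def write_gaf(doc: GafDocument, stream: IO[str]) -> None:
    """Write a :class:`GafDocument`; inverse of :func:`read_gaf`."""
    header = list(doc.header_lines)
    version_line = f"!gaf-version: {doc.version}"
    if not header or not header[0].startswith("!gaf-version:"):
        header.insert(0, version_line)
    for line in header:
        stream.write(line + "\n")
    for index, ann in enumerate(doc.annotations, start=1):
        _check_mandatory(ann, index)
        stream.write("\t".join(_gaf_row(ann)) + "\n")


def write_gpad(doc: GafDocument, stream: IO[str]) -> None:
    """Emit GPAD 1.1 (12 columns), dropping the gene-object metadata columns.

    A record with no relation qualifier gets the GAF 2.2 default for its
    aspect; a bare ``NOT`` becomes ``NOT|<default relation>``.
    """
    stream.write("!gpa-version: 1.1\n")
    for index, ann in enumerate(doc.annotations, start=1):
        _check_mandatory(ann, index)
        quals = list(ann.qualifiers)
        relations = [q for q in quals if q != "NOT"]
        if not relations:
            default = DEFAULT_RELATION_BY_ASPECT.get(ann.aspect)
            if default:
                quals = quals + [default]
        interacting = ann.taxon[1] if len(ann.taxon) > 1 else ""
        row = [
            ann.db,
            ann.db_object_id,
            "|".join(quals),
            ann.go_id,
            "|".join(ann.references),
            ann.evidence_code,
            "|".join(ann.with_from),
            interacting,
            ann.date,
            ann.assigned_by,
            ann.annotation_extension,
            "",  # annotation properties: none carried by GAF input
        ]
        stream.write("\t".join(row) + "\n")


def dedupe(annotations: Sequence[Annotation]) -> list[Annotation]:
    """Drop records identical on the annotation identity key, keeping first.

    The key is (db, db_object_id, qualifiers, go_id, evidence_code,
    with_from, references); order of survivors is preserved.
    """
    seen: set[tuple] = set()
    out: list[Annotation] = []
    for ann in annotations:
        key = (
            ann.db,
            ann.db_object_id,
            tuple(ann.qualifiers),
            ann.go_id,
            ann.evidence_code,
            tuple(ann.with_from),
            tuple(ann.references),
        )
        if key in seen:
            continue
        seen.add(key)
        out.append(ann)
    return out


def experimental_annotations(annotations: Iterable[Annotation]) -> list[Annotation]:
    """Records whose evidence code is in the experimental method class."""
    return [
        a
        for a in annotations
        if classify_evidence(a.evidence_code).method_class == "experimental"
    ]
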