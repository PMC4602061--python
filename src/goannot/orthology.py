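"""HomoloGene-style orthology classes and the cardinality queries on them.

An orthology class is a set of (taxon, gene) members across species,
read from the HomoloGene flat-file dialect::

    HID <tab> TaxID <tab> GeneID <tab> Symbol [<tab> ProteinGI <tab> ProteinAcc]

Transfer eligibility hinges on two questions this module answers: which
genes of a target taxon sit in the same class as a given gene
(:func:`partners`), and whether a class is "many-to-many" — some species
contributes more than one gene — which restricts biological-process
transfer (:func:`is_many_to_many`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable

from goannot.errors import ParseError, ValidationError


@dataclass(frozen=True)
class ClassMember:
    taxon_id: int
    gene_id: str
    symbol: str = ""


@dataclass
class OrthologyClass:
    class_id: str
    members: list[ClassMember] = field(default_factory=list)

    def taxa(self) -> set[int]:
        return {m.taxon_id for m in self.members}

    def genes_of(self, taxon_id: int) -> list[ClassMember]:
        return [m for m in self.members if m.taxon_id == taxon_id]


@dataclass
class OrthologySet:
    classes: dict[str, OrthologyClass] = field(default_factory=dict)
    index: dict[tuple[int, str], str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.classes)

    def class_of(self, taxon_id: int, gene_id: str) -> OrthologyClass | None:
        cid = self.index.get((taxon_id, gene_id))
        return self.classes[cid] if cid is not None else None

    def add_member(self, class_id: str, member: ClassMember) -> None:
        key = (member.taxon_id, member.gene_id)
        existing = self.index.get(key)
        if existing is not None and existing != class_id:
            raise ValidationError(
                f"gene ({member.taxon_id}, {member.gene_id}) appears in classes "
                f"{existing} and {class_id}"
            )
        cls = self.classes.setdefault(class_id, OrthologyClass(class_id=class_id))
        if existing is None:
            cls.members.append(member)
            self.index[key] = class_id


def read_homologene(stream: IO[str]) -> OrthologySet:
    """Parse the HomoloGene flat-file dialect into an :class:`OrthologySet`.

    Requires >= 4 tab-separated columns per line; columns beyond the
    fourth (protein GI / accession) are ignored. A gene listed in two
    different classes raises :class:`ValidationError` naming both.
    """
    out = OrthologySet()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise ParseError(
                f"expected >= 4 tab-separated columns, got {len(cols)}", line=lineno
            )
        class_id, taxon_text, gene_id, symbol = cols[0], cols[1], cols[2], cols[3]
        try:
            taxon_id = int(taxon_text)
        except ValueError:
            raise ParseError(f"non-integer taxon id {taxon_text!r}", line=lineno) from None
        out.add_member(class_id, ClassMember(taxon_id=taxon_id, gene_id=gene_id, symbol=symbol))
    return out


def is_many_to_many(cls: OrthologyClass, taxa: Iterable[int] | None = None) -> bool:
    """True iff some taxon contributes >= 2 genes to the class.

    ``taxa`` restricts the check to the given species (the species-pair
    scope of the transfer configuration); by default all species in the
    class count.
    """
    counts = Counter(m.taxon_id for m in cls.members)
    if taxa is None:
        return any(n >= 2 for n in counts.values())
    return any(counts[t] >= 2 for t in taxa)


def partners(
    ortho: OrthologySet, taxon: int, gene: str, target_taxon: int
) -> list[str]:
    """Gene ids of ``target_taxon`` in the class containing (taxon, gene).

    Empty when the gene is unclassified or the class has no target-taxon
    member. A gene is not its own partner unless listed twice, which the
    uniqueness invariant forbids; same-taxon queries return the *other*
    co-members plus the gene itself as stored (callers filter as needed).
    """
    cls = ortho.class_of(taxon, gene)
    if cls is None:
        return []
    return [m.gene_id for m in cls.members if m.taxon_id == target_taxon]
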