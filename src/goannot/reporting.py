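"""Method-class summaries and GO-slim charts over annotation sets.

Two overview tools model-organism databases publish for their users:

* :func:`summarize_by_method` — per method class (manual/experimental
  curation, sequence similarity, phylogenetic, electronic), how many
  distinct genes and annotations; plus the genes annotated *only* by
  inferred methods (no experimental record at all), which measures how
  much knowledge the comparative pipelines contribute beyond direct
  experiment.
* :func:`slim_chart` — bin annotations into a GO slim (a curated set of
  high-level terms) via minimal-cover mapping, counting distinct genes
  and annotations per slim term, optionally excluding IEA records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from goannot.gaf_io import GafDocument, classify_evidence
from goannot.ontology import Ontology, SlimSet, map_to_slim

INFERRED_CLASSES = ("sequence_similarity", "phylogenetic", "electronic")
METHOD_CLASSES = ("experimental",) + INFERRED_CLASSES + ("other",)

UNMAPPED = "unmapped"


@dataclass
class MethodSummary:
    """Counts per method class, in the shape of a published summary table.

    ``genes``/``annotations``: per method class. ``only_by_genes`` /
    ``only_by_annotations``: restricted to genes with no experimental
    record anywhere in the document (per inferred class, a gene may appear
    under several classes). ``total_*`` count each distinct gene once.
    ``by_provider`` breaks each method class down by the assigning
    resource (GAF column 15).
    """

    genes: dict[str, int] = field(default_factory=dict)
    annotations: dict[str, int] = field(default_factory=dict)
    only_by_genes: dict[str, int] = field(default_factory=dict)
    only_by_annotations: dict[str, int] = field(default_factory=dict)
    total_genes: int = 0
    total_annotations: int = 0
    total_only_by_genes: int = 0
    total_only_by_annotations: int = 0
    by_provider: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method_class": cls,
                "genes": self.genes.get(cls, 0),
                "annotations": self.annotations.get(cls, 0),
                "only_by_genes": self.only_by_genes.get(cls, 0),
                "only_by_annotations": self.only_by_annotations.get(cls, 0),
            }
            for cls in METHOD_CLASSES
        ]
        rows.append(
            {
                "method_class": "total",
                "genes": self.total_genes,
                "annotations": self.total_annotations,
                "only_by_genes": self.total_only_by_genes,
                "only_by_annotations": self.total_only_by_annotations,
            }
        )
        return pd.DataFrame(rows)


def summarize_by_method(doc: GafDocument) -> MethodSummary:
    """Classify every record by evidence method class and count."""
    summary = MethodSummary()
    genes_by_class: dict[str, set] = {cls: set() for cls in METHOD_CLASSES}
    ann_by_class: dict[str, int] = {cls: 0 for cls in METHOD_CLASSES}
    ann_by_class_gene: dict[str, dict] = {cls: {} for cls in METHOD_CLASSES}
    provider: dict[str, dict[str, int]] = {}

    for ann in doc.annotations:
        cls = classify_evidence(ann.evidence_code).method_class
        genes_by_class[cls].add(ann.gene_key)
        ann_by_class[cls] += 1
        ann_by_class_gene[cls][ann.gene_key] = ann_by_class_gene[cls].get(ann.gene_key, 0) + 1
        if ann.assigned_by:
            provider.setdefault(cls, {}).setdefault(ann.assigned_by, 0)
            provider[cls][ann.assigned_by] += 1

    experimental_genes = genes_by_class["experimental"]
    all_genes = set().union(*genes_by_class.values()) if doc.annotations else set()
    inferred_only = {
        g
        for cls in INFERRED_CLASSES
        for g in genes_by_class[cls]
        if g not in experimental_genes
    }

    for cls in METHOD_CLASSES:
        summary.genes[cls] = len(genes_by_class[cls])
        summary.annotations[cls] = ann_by_class[cls]
    for cls in INFERRED_CLASSES:
        only = {g for g in genes_by_class[cls] if g not in experimental_genes}
        summary.only_by_genes[cls] = len(only)
        summary.only_by_annotations[cls] = sum(
            n for g, n in ann_by_class_gene[cls].items() if g in only
        )

    summary.total_genes = len(all_genes)
    summary.total_annotations = len(doc.annotations)
    summary.total_only_by_genes = len(inferred_only)
    summary.total_only_by_annotations = sum(
        sum(n for g, n in ann_by_class_gene[cls].items() if g in inferred_only)
        for cls in INFERRED_CLASSES
    )
    summary.by_provider = provider
    return summary


def slim_chart(
    doc: GafDocument,
    ontology: Ontology,
    slim: SlimSet,
    exclude_iea: bool = False,
    include_not: bool = False,
) -> pd.DataFrame:
    """Bin annotations into a GO slim.

    Returns a frame with one row per slim term — columns ``slim_term``,
    ``name``, ``aspect``, ``gene_count`` (distinct genes), and
    ``annotation_count`` (a record covered by k slim terms contributes to
    k rows) — plus an ``unmapped`` row for records no slim term covers.
    NOT-qualified records are excluded unless ``include_not``; IEA records
    are excluded when ``exclude_iea``.
    """
    slim.validate(ontology)
    genes: dict[str, set] = {t: set() for t in slim.term_ids}
    counts: dict[str, int] = {t: 0 for t in slim.term_ids}
    genes[UNMAPPED] = set()
    counts[UNMAPPED] = 0

    for ann in doc.annotations:
        if ann.is_not and not include_not:
            continue
        if exclude_iea and ann.evidence_code == "IEA":
            continue
        if ann.go_id not in ontology:
            covering: set[str] = set()
        else:
            covering = map_to_slim(ontology, ann.go_id, slim)
        if not covering:
            genes[UNMAPPED].add(ann.gene_key)
            counts[UNMAPPED] += 1
            continue
        for term in covering:
            genes[term].add(ann.gene_key)
            counts[term] += 1

    rows = []
    for term in sorted(slim.term_ids):
        t = ontology.term(term)
        rows.append(
            {
                "slim_term": term,
                "name": t.name,
                "aspect": t.aspect,
                "gene_count": len(genes[term]),
                "annotation_count": counts[term],
            }
        )
    rows.append(
        {
            "slim_term": UNMAPPED,
            "name": "(no covering slim term)",
            "aspect": "",
            "gene_count": len(genes[UNMAPPED]),
            "annotation_count": counts[UNMAPPED],
        }
    )
    return pd.DataFrame(rows)
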