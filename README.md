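# goannot — comparative Gene Ontology annotation toolkit

Most genes in most genomes will never be experimentally characterized.
Model-organism databases therefore extend the experimentally grounded GO
annotations they curate to other species through three comparative
pipelines, each with its own evidence code and its own safety rules.
`goannot` implements that machinery as a reusable Python library with a
thin command-line interface, for curators, annotation-pipeline engineers
and computational biologists who need to run, audit or simulate these
inferences rather than just consume their output.

## What it implements

**Orthology-based transfer (ISO).** Experimental annotations of a source
species (say human or rat) become `ISO` ("inferred from sequence
orthology") records for the orthologous genes of a target species (say
mouse), driven by HomoloGene-style many-to-many orthology classes. A
source record survives a fixed-order rule cascade or is rejected with a
machine-readable reason:

1. only experimental evidence (`EXP/IDA/IPI/IMP/IGI/IEP`) transfers —
   inferred evidence is never re-transferred, preventing circular
   annotation between resources;
2. `NOT`-qualified records never transfer;
3. protein binding (`GO:0005515`) never transfers — it describes a
   specific binding event, not a conserved property;
4. the source gene must sit in an orthology class with ≥ 1 target gene;
5. in a *many-to-many* class (some species contributes ≥ 2 genes) only
   molecular-function (F) and cellular-component (C) annotations
   transfer; biological-process (P) records are rejected;
6. a term is blocked class-wide when any class member, in any species,
   carries a `NOT` annotation to it;
7. optionally, target genes already holding the term experimentally are
   skipped.

The reverse direction (`reverse_export`) converts curated `ISO/ISA/ISS`
records back into experimental annotations of their with/from gene,
citing the original publication — the form in which orthology curation
is shared with the source species' annotation resource.

**Phylogenetic propagation (IBD/IBA).** Experimental annotations are
overlaid on a gene tree; an assertion that term *T* is ancestral at node
*N* yields one `IBD` record at *N* and one `IBA` record at every
descendant leaf that does not already hold *T* experimentally, is not
under a curator block (`IKR`/`IRD`) on the path *N*→leaf, and has no
experimental `NOT` to *T*. An MRCA heuristic proposes candidate
assertions; applying them remains a curation decision.

**Electronic annotation (IEA).** A generic external2go mapping engine
(EC numbers, Swiss-Prot keywords, InterPro domains) joins mapping rules
against a gene feature table and emits deduplicated `IEA` records.

**Reporting.** Method-class summaries (genes/annotations per evidence
class, plus genes annotated *only* by inferred methods) and GO-slim
charts with minimal-cover term mapping and optional IEA exclusion.

All exchange happens in the standard formats: OBO ontologies, GAF
2.1/2.2 (bit-exact round trip), GPAD 1.1, HomoloGene flat files, Newick
gene trees. A seeded fixture generator (`goannot.fixtures`) produces
coherent synthetic bundles so every pipeline runs without downloads.

## Worked example

```bash
python examples/01_orthology_transfer.py
```

prints, for the seed-1 synthetic bundle (504 human annotations, 100
orthology classes):

```
evaluated 504 human annotations
accepted  126, produced 127 mouse ISO records
rejection reasons:
  bp_in_many_to_many                  19
  duplicate_of_experimental           3
  no_orthology_class                  113
  no_target_partner                   33
  not_experimental                    174
  not_qualifier                       21
  ok                                  126
  protein_binding                     15

first produced record:
  MGI:G10090_0128 GO:0000009 ISO with/from=UniProtKB:G9606_0072 ref=GO_REF:0000096
```

Reading it: of 504 evaluated source records, 174 were rejected because
their evidence was itself inferred (rule 1), 21 carried `NOT`, 15 were
protein-binding, 19 were biological-process records inside many-to-many
classes, and 146 had no usable orthology partner; the 126 accepted
records fanned out to 127 mouse ISO records (one accepted many-to-many
record can produce several). Each produced record names the source gene
in with/from and the load reference marking it as orthology-derived.
The other `examples/` scripts walk through propagation, IEA generation,
reporting and reverse export the same way. The equivalent shell
pipeline is `goannot fixtures` → `goannot transfer ... --report r.json`;
every CLI run writes a manifest JSON with input digests beside its
output.

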