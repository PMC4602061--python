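# Methods

## The model

`goannot` treats comparative GO annotation as three deterministic
inference procedures over four kinds of input: a GO DAG, annotation sets
(GAF), orthology classes (HomoloGene flat-file dialect) and rooted gene
trees (Newick). None of the procedures is statistical; each is a rule
system whose value lies in being exactly auditable, so the package's
central design commitment is determinism: given the same inputs and a
pinned run date, every pipeline produces byte-identical output, and
every rejection carries a machine-readable reason.

### Orthology transfer (ISO)

An annotation of a source-species gene is eligible for transfer to the
orthologous genes of a target species only if it is experimental.
Restricting sources to experimental evidence is what prevents circular
annotation: an `ISO` record imported from resource A must never become
evidence for a new inferred record exported back to A. The cascade
order is fixed (evidence class, `NOT` qualifier, protein binding,
orthology membership, target partner, many-to-many/aspect, class-wide
`NOT` block, experimental duplicate) and the first failing rule is the
recorded reason; the order is a package choice made so that reason
tallies are reproducible — the rules themselves are order-independent
for acceptance, only the reported reason depends on it.

Two rules deserve expansion:

* **Many-to-many aspect restriction.** When a class contains two or
  more genes from one species, paralog divergence makes process-level
  conservation unreliable, so only molecular-function and
  cellular-component annotations transfer. By default cardinality is
  evaluated over *all* species in the class (the conservative reading);
  `many_to_many_scope="species_pair"` restricts it to the source/target
  pair.
* **Class-wide `NOT` blocking.** A `NOT` annotation on any class
  member, in any species and under any evidence class, blocks transfer
  of exactly that term to every member. Matching is exact-term;
  `block_descendant_terms=True` extends the block down the is_a/part_of
  closure for users who consider a negated ancestor to negate its
  specializations.

The taxon guard in `evaluate` fires *after* the evidence-class rule:
records violating the configured source taxon are a usage error only if
they are experimental. This makes re-feeding a pipeline's own inferred
output (target-taxon `ISO` records) safely idempotent rather than an
error, which is the anti-circularity property the test suite asserts.

Duplicate suppression against existing target-species experimental
annotations defaults on: an inferred record adds nothing where direct
evidence exists, and suppressing it keeps the produced file minimal.
It is a config switch because some consumers prefer the redundant
record for provenance completeness.

`reverse_export` inverts curated `ISO/ISA/ISS` records. The annotation
key for the evidence map is `(db, db_object_id, go_id)`; the evidence
map supplies the experimental code and publication the curator read,
and a with/from→taxon mapping supplies the subject's taxon, since a GAF
record carries no taxon for its with/from gene.

### Phylogenetic propagation (IBD/IBA)

Propagation is a pure path walk, deliberately ontology-agnostic: "leaf
already annotated to the term" means *exactly* that term, with no
closure over the DAG (a closure option is a natural extension but
defaults off, because skipping a leaf annotated to a descendant term
would silently discard the more general ancestral assertion). A block
at node *M* suppresses the entire subtree of *M* for that term; a block
at the assertion node itself yields an empty propagation and a warning
rather than an error, since the curator may intend exactly that. An
experimental `NOT` at a leaf acts as a single-leaf block recorded with
reason `NOT`. Every assertion yields exactly one `IBD` record, so per
assertion the descendant leaves partition exactly into {experimental,
blocked, IBA} — the conservation identity the acceptance checks verify.

`IBD` subjects are internal tree nodes, which have no NCBI taxon; those
records carry `taxon:1` (the taxonomy root) since GAF requires the
column. `IBA` with/from is composed as ancestor label + supporter gene
ids for auditability. The MRCA proposer is a pre-curation aid only:
with fewer than `min_supporters` (default 2) experimentally annotated
leaves there is no comparative signal worth asserting.

One dialect note: tree leaves are labeled `TAXON|DB:GENEID`, but the
assertions TSV pipe-joins its supporters column, so supporters are
written as the pipe-free `DB:GENEID` token; the tree resolves either
form.

### Electronic annotation (IEA)

A single relational join serves the EC, Swiss-Prot-keyword and InterPro
pipelines: which external identifiers a gene carries is an *input*
(feature table), never computed. Rules whose GO term is unknown or
obsolete in the supplied ontology are dropped with a logged count — a
mapping file typically lags the ontology, and silently emitting dead
terms would poison downstream slim charts.

### Ontology and reporting

Closure traverses is_a and part_of only — the conventional GO-slim
closure; regulates-type relationships are parsed and ignored with a
warning. Obsolete terms are kept for lookup (so validation can flag
them) but never participate in closure; alt_ids resolve silently to
their primary accession. Slim mapping returns the full minimal cover
(an antichain), not a single term, so no tie-break is needed; a record
covered by *k* slim terms contributes *k* annotation counts, and
records covered by none are tallied in an explicit `unmapped` row.
`NOT`-qualified records are excluded from slim charts by default
(standard slim-tool behavior, overridable). In the method summary,
"only by" counts cover genes with zero experimental records; a gene may
appear under several inferred classes but is counted once in the
distinct-gene totals.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `protein_binding_term` | `GO:0005515` | excluded exactly, not its descendants — the rationale targets the generic binding event; descendants carry transferable specificity |
| `suppress_if_experimental_duplicate` | `True` | skip targets already holding the term experimentally |
| `many_to_many_scope` | `full_class` | taxa counted for the cardinality rule |
| `block_descendant_terms` | `False` | extend class-wide `NOT` blocks via closure |
| `min_supporters` (MRCA proposer) | 2 | experimental leaves required to propose an assertion |
| run date | today, injectable | the only non-input-derived field in produced records; pin it for byte-identical runs |

## The synthetic-data generator

`goannot.fixtures` emulates the *structure* of the real inputs at desk
scale: three taxa (mouse 10090 as target, human 9606 and rat 10116 as
sources); 100 orthology classes with a 30 % many-to-many rate
(one-to-one orthology still dominates real vertebrate classes, but the
many-to-many minority is where the interesting rules fire, so it is
over-represented relative to the < 10 % seen in nature); 500 human
source annotations (the primary transfer direction) and half that for
the other taxa; an evidence mix of 65 % experimental (IDA/IMP/IPI),
15 % ISO and 20 % IEA; a 5 % `NOT` rate (high enough that class-wide
blocking is exercised in every bundle); ~10 terms per aspect with the
real aspect-root accessions and a protein-binding term; a 32-leaf gene
tree whose assertion supporters receive injected experimental records.
One seed drives everything; each file type derives its stream by a
fixed offset so adding a file type never perturbs existing ones.

What it does **not** emulate: real identifiers or term semantics, taxon
constraints, annotation-extension content, isoform-specific annotation,
the size of production files (10⁵–10⁶ records), or curation noise
(typos, retracted papers, inconsistent qualifiers). Passing tests
therefore demonstrate rule-engine correctness and format fidelity, not
robustness to the pathologies of real curation data.

## Numerical and degenerate-input choices

* GAF round trips are byte-exact: dates are validated but never
  reformatted, field order and pipe-joining are canonical, and header
  lines are preserved verbatim.
* GPAD output defaults missing relation qualifiers per aspect
  (F→`enables`, P→`involved_in`, C→`located_in`), the published GAF 2.2
  defaults; input qualifiers are preserved when present.
* Evidence codes are GO mnemonics, not ECO identifiers; unlisted codes
  classify as `other`, keeping classification total.
* Empty documents, empty orthology streams, assertion-free propagation
  and comment-only mapping files all return empty results rather than
  errors; malformed lines raise errors naming the line or stanza.
* Cycle detection on the is_a graph reports one concrete cycle.
* Problem sizes in tests and the acceptance script (20 bundles of ~500
  source annotations and 100 classes; 5 propagation bundles; 50-record
  round-trip documents) were chosen as the smallest sizes at which
  every rule and blocking path fires in every bundle.

## Known limitations

* No taxon-constraint checking: a transferred term biologically
  impossible in the target taxon is not flagged.
* Column 16 (annotation extensions) is opaque; conjunctive with/from
  (comma-separated) is treated as one token.
* Orthology classes and gene trees are inputs; the package neither
  infers orthology nor builds trees.
* The NOT-blocking and duplicate-suppression defaults encode the
  stricter reading wherever the conventions leave room (blocking
  consults all evidence classes, cardinality counts all species);
  both are configurable but the defaults are opinionated toward safety.
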