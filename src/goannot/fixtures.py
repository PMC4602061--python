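"""Seeded generator of coherent synthetic inputs for every pipeline.

One :class:`FixtureSpec` produces a mutually consistent bundle: an OBO
ontology (three aspect DAGs with the real aspect-root accessions and a
protein-binding term), HomoloGene-style orthology classes over mouse,
human and rat gene pools, GAF annotation sets per taxon, a Newick gene
tree over a sample of those genes with assertion/block TSVs, an
external2go mapping with a gene feature table, and a slim file.

Identifiers are synthetic (no real gene symbols or term names); the point
is structural realism — a DAG that is acyclic and rooted, classes whose
many-to-many fraction is controlled, annotation evidence drawn from a
stated mix, NOT qualifiers at a stated rate — not biological content.

Determinism: a single integer seed drives everything; each file type
derives its own stream from the seed by a fixed offset, so adding a new
file type never perturbs the existing ones.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from goannot.errors import ValidationError
from goannot.gaf_io import DEFAULT_RELATION_BY_ASPECT

#: canonical aspect root accessions
ROOTS = {"F": "GO:0003674", "P": "GO:0008150", "C": "GO:0005575"}
PROTEIN_BINDING = "GO:0005515"

DBS = {10090: "MGI", 9606: "UniProtKB", 10116: "RGD"}

# fixed offsets for per-file sub-streams
_OFF_OBO, _OFF_ORTHO, _OFF_GAF, _OFF_TREE, _OFF_MAP, _OFF_SLIM = 1, 2, 3, 4, 5, 6


def _rng(seed: int, offset: int) -> random.Random:
    return random.Random(seed * 1_000_003 + offset)


@dataclass
class FixtureSpec:
    """Size and composition knobs for one synthetic bundle.

    Defaults describe a desk-scale study: three taxa (mouse as target,
    human and rat as sources), 100 orthology classes of which about 30 %
    are many-to-many, 500 human source annotations with a 5 % NOT rate,
    and a 32-leaf gene tree.
    """

    seed: int = 1
    n_terms: int = 10  # per aspect, root included
    n_classes: int = 100
    frac_many_to_many: float = 0.3
    n_genes_per_taxon: int = 160
    n_annotations: int = 500
    evidence_mix: dict[str, float] = field(
        default_factory=lambda: {"IDA": 0.35, "IMP": 0.20, "IPI": 0.10, "ISO": 0.15, "IEA": 0.20}
    )
    frac_not: float = 0.05
    tree_leaves: int = 32
    target_taxon: int = 10090
    source_taxa: tuple[int, ...] = (9606, 10116)
    gaf_version: str = "2.2"

    def validate(self) -> None:
        if not 0 <= self.frac_many_to_many <= 1 or not 0 <= self.frac_not <= 1:
            raise ValidationError("proportions must lie in [0, 1]")
        if abs(sum(self.evidence_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("evidence mix must sum to 1")
        if self.frac_many_to_many > 0 and self.n_genes_per_taxon < 2:
            raise ValidationError(
                "many-to-many classes need at least 2 genes per taxon"
            )
        if self.n_genes_per_taxon < self.n_classes:
            raise ValidationError(
                "need at least one gene per taxon per orthology class"
            )
        if self.n_terms < 2:
            raise ValidationError("need at least a root and one child per aspect")
        if self.gaf_version not in {"2.1", "2.2"}:
            raise ValidationError(f"unsupported gaf_version {self.gaf_version}")


@dataclass
class FixtureBundle:
    """All generated texts plus bookkeeping about the draws made."""

    obo: str
    homologene: str
    gaf_by_taxon: dict[int, str]
    newick: str
    assertions_tsv: str
    blocks_tsv: str
    mapping: str
    features_tsv: str
    slim: str
    meta: dict = field(default_factory=dict)

    def write_to(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def put(name: str, text: str) -> None:
            path = out / name
            path.write_text(text)
            paths[name] = path

        put("ontology.obo", self.obo)
        put("homologene.data", self.homologene)
        for taxon, text in self.gaf_by_taxon.items():
            put(f"annotations.{taxon}.gaf", text)
        put("genetree.nwk", self.newick)
        put("assertions.tsv", self.assertions_tsv)
        put("blocks.tsv", self.blocks_tsv)
        put("mapping2go.txt", self.mapping)
        put("features.tsv", self.features_tsv)
        put("goslim.txt", self.slim)
        return paths


def _gene_pools(spec: FixtureSpec) -> dict[int, list[str]]:
    taxa = (spec.target_taxon, *spec.source_taxa)
    return {
        t: [f"G{t}_{i:04d}" for i in range(spec.n_genes_per_taxon)] for t in taxa
    }


def _db(taxon: int) -> str:
    return DBS.get(taxon, f"DB{taxon}")


def _make_obo(spec: FixtureSpec) -> tuple[str, dict[str, str], list[str]]:
    """Returns (obo text, term->aspect for live non-root terms, obsolete ids)."""
    rng = _rng(spec.seed, _OFF_OBO)
    lines = ["format-version: 1.2", "ontology: go-fixture", ""]
    aspect_ns = {
        "F": "molecular_function",
        "P": "biological_process",
        "C": "cellular_component",
    }
    live: dict[str, str] = {}
    obsolete: list[str] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        acc = f"GO:{counter:07d}"
        while acc in ROOTS.values() or acc == PROTEIN_BINDING:
            counter += 1
            acc = f"GO:{counter:07d}"
        return acc

    for aspect, root in ROOTS.items():
        lines += [
            "[Term]",
            f"id: {root}",
            f"name: {aspect_ns[aspect]}",
            f"namespace: {aspect_ns[aspect]}",
            "",
        ]
        terms = [root]
        if aspect == "F":
            lines += [
                "[Term]",
                f"id: {PROTEIN_BINDING}",
                "name: protein binding",
                "namespace: molecular_function",
                f"is_a: {root}",
                "",
            ]
            terms.append(PROTEIN_BINDING)
            live[PROTEIN_BINDING] = "F"
        n_children = spec.n_terms - len(terms)
        for i in range(n_children):
            acc = next_id()
            stanza = [
                "[Term]",
                f"id: {acc}",
                f"name: synthetic {aspect} term {i + 1}",
                f"namespace: {aspect_ns[aspect]}",
            ]
            parents = rng.sample(terms, k=min(len(terms), 1 + (rng.random() < 0.3)))
            stanza.append(f"is_a: {parents[0]}")
            if len(parents) > 1:
                if rng.random() < 0.5:
                    stanza.append(f"is_a: {parents[1]}")
                else:
                    stanza.append(f"relationship: part_of {parents[1]}")
            if rng.random() < 0.15:
                alt = next_id()
                stanza.append(f"alt_id: {alt}")
            lines += stanza + [""]
            terms.append(acc)
            live[acc] = aspect
        # one obsolete term per aspect, excluded from annotation pools
        acc = next_id()
        lines += [
            "[Term]",
            f"id: {acc}",
            f"name: obsolete {aspect} term",
            "is_obsolete: true",
            "",
        ]
        obsolete.append(acc)
    return "\n".join(lines), live, obsolete


def _make_orthology(
    spec: FixtureSpec, pools: dict[int, list[str]]
) -> tuple[str, dict[str, list[tuple[int, str]]], int]:
    rng = _rng(spec.seed, _OFF_ORTHO)
    taxa = (spec.target_taxon, *spec.source_taxa)
    cursors = {t: iter(rng.sample(pools[t], len(pools[t]))) for t in taxa}
    classes: dict[str, list[tuple[int, str]]] = {}
    n_m2m = 0
    lines: list[str] = []
    for i in range(spec.n_classes):
        cid = str(1000 + i)
        members: list[tuple[int, str]] = []
        chosen = [t for t in taxa if rng.random() < 0.85]
        if len(chosen) < 2:
            chosen = list(rng.sample(taxa, 2))
        for t in chosen:
            members.append((t, next(cursors[t])))
        if spec.frac_many_to_many > 0 and rng.random() < spec.frac_many_to_many:
            t = rng.choice(chosen)
            try:
                members.append((t, next(cursors[t])))
                n_m2m += 1
            except StopIteration:
                raise ValidationError("gene pool exhausted while building classes") from None
        classes[cid] = members
        for t, g in members:
            lines.append(f"{cid}\t{t}\t{g}\tsym_{g}\t{rng.randrange(10**7)}\tNP_{g}")
    if spec.frac_many_to_many > 0 and spec.n_classes >= 1 and n_m2m == 0:
        # guarantee at least one many-to-many class
        cid = next(iter(classes))
        t = classes[cid][0][0]
        extra = next(cursors[t])
        classes[cid].append((t, extra))
        lines.append(f"{cid}\t{t}\t{extra}\tsym_{extra}\t{rng.randrange(10**7)}\tNP_{extra}")
        n_m2m = 1
    return "\n".join(lines) + "\n", classes, n_m2m


def _gaf_text(spec: FixtureSpec, records: list[list[str]]) -> str:
    header = [f"!gaf-version: {spec.gaf_version}", "!generated-by: goannot fixtures"]
    return "\n".join(header + ["\t".join(r) for r in records]) + "\n"


def _make_annotations(
    spec: FixtureSpec,
    pools: dict[int, list[str]],
    live_terms: dict[str, str],
) -> tuple[dict[int, list[list[str]]], random.Random]:
    rng = _rng(spec.seed, _OFF_GAF)
    terms = sorted(live_terms)
    codes = sorted(spec.evidence_mix)
    weights = [spec.evidence_mix[c] for c in codes]
    taxa = (spec.target_taxon, *spec.source_taxa)
    counts = {spec.source_taxa[0]: spec.n_annotations}
    for t in taxa:
        counts.setdefault(t, spec.n_annotations // 2)

    by_taxon: dict[int, list[list[str]]] = {}
    for taxon in taxa:
        records: list[list[str]] = []
        db = _db(taxon)
        for _ in range(counts[taxon]):
            gene = rng.choice(pools[taxon])
            term = rng.choice(terms)
            aspect = live_terms[term]
            code = rng.choices(codes, weights=weights, k=1)[0]
            is_not = rng.random() < spec.frac_not
            if spec.gaf_version == "2.2":
                quals = ["NOT"] if is_not else []
                quals.append(DEFAULT_RELATION_BY_ASPECT[aspect])
            else:
                quals = ["NOT"] if is_not else []
            with_from = ""
            if code == "ISO":
                other = rng.choice([t for t in taxa if t != taxon])
                with_from = f"{_db(other)}:{rng.choice(pools[other])}"
            elif code == "IEA":
                with_from = f"InterPro:IPR{rng.randrange(1, 11):06d}"
            ref = f"PMID:{rng.randrange(10**6, 10**7)}"
            records.append(
                [
                    db,
                    gene,
                    f"sym_{gene}",
                    "|".join(quals),
                    term,
                    ref,
                    code,
                    with_from,
                    aspect,
                    "",
                    "",
                    "gene",
                    f"taxon:{taxon}",
                    "20150601",
                    "goannot-fixtures",
                    "",
                    "",
                ]
            )
        by_taxon[taxon] = records
    return by_taxon, rng


def _make_tree(
    spec: FixtureSpec,
    pools: dict[int, list[str]],
    live_terms: dict[str, str],
    gaf_records: dict[int, list[list[str]]],
) -> tuple[str, str, str]:
    """Build the Newick tree plus assertion and block TSVs.

    Some tree leaves receive injected experimental annotations (appended
    to their taxon's GAF) so that every assertion has real supporters.
    """
    rng = _rng(spec.seed, _OFF_TREE)
    taxa = (spec.target_taxon, *spec.source_taxa)
    leaf_ids: list[tuple[int, str]] = []
    per = max(1, spec.tree_leaves // len(taxa))
    for t in taxa:
        leaf_ids += [(t, g) for g in rng.sample(pools[t], per)]
    leaf_ids = leaf_ids[: spec.tree_leaves]
    rng.shuffle(leaf_ids)

    labels = [f"{t}|{_db(t)}:{g}" for t, g in leaf_ids]
    counter = 0
    parent_map: dict[str, str] = {}
    children: dict[str, list[str]] = {}

    def build(items: list[str]) -> str:
        nonlocal counter
        if len(items) == 1:
            return items[0]
        split = rng.randrange(1, len(items))
        left, right = build(items[:split]), build(items[split:])
        counter += 1
        node = f"N{counter}"
        children[node] = [left, right]
        parent_map[left] = node
        parent_map[right] = node
        return node

    root = build(labels)

    def newick(node: str) -> str:
        if node not in children:
            return f"'{node}'"
        return "(" + ",".join(newick(c) for c in children[node]) + ")" + node

    newick_text = newick(root) + ";"

    # inject experimental support for a few terms and assert at the MRCA
    exp_terms = rng.sample(sorted(live_terms), k=min(3, len(live_terms)))
    assertion_lines: list[str] = []
    block_lines: list[str] = []
    identity = {lab: (t, g) for lab, (t, g) in zip(labels, leaf_ids)}

    def mrca(nodes: list[str]) -> str:
        def lineage(n: str) -> list[str]:
            chain = [n]
            while n in parent_map:
                n = parent_map[n]
                chain.append(n)
            return chain

        common = set(lineage(nodes[0]))
        for n in nodes[1:]:
            common &= set(lineage(n))
        for n in lineage(nodes[0]):
            if n in common:
                return n
        raise AssertionError("disconnected tree")

    for term in exp_terms:
        supporters = rng.sample(labels, k=min(3, len(labels)))
        for lab in supporters:
            taxon, gene = identity[lab]
            aspect = live_terms[term]
            quals = (
                [DEFAULT_RELATION_BY_ASPECT[aspect]] if spec.gaf_version == "2.2" else []
            )
            gaf_records[taxon].append(
                [
                    _db(taxon),
                    gene,
                    f"sym_{gene}",
                    "|".join(quals),
                    term,
                    f"PMID:{rng.randrange(10**6, 10**7)}",
                    "IDA",
                    "",
                    aspect,
                    "",
                    "",
                    "gene",
                    f"taxon:{taxon}",
                    "20150601",
                    "goannot-fixtures",
                    "",
                    "",
                ]
            )
        node = mrca(supporters)
        # supporters are written as DB:GENEID tokens: the TSV column is
        # pipe-joined, and full leaf labels themselves contain a pipe
        tokens = ["{}:{}".format(_db(identity[s][0]), identity[s][1]) for s in supporters]
        assertion_lines.append(f"{node}\t{term}\t" + "|".join(tokens))
        # sometimes block a sub-branch that holds no supporter
        if rng.random() < 0.6:
            candidates = [
                n
                for n in children
                if n != node
                and _under(parent_map, n, node)
                and not any(_under(parent_map, s, n) or s == n for s in supporters)
            ]
            if candidates:
                block_lines.append(
                    f"{rng.choice(candidates)}\t{term}\t{rng.choice(['IKR', 'IRD'])}"
                )

    return newick_text, "\n".join(assertion_lines) + "\n", "\n".join(block_lines) + ("\n" if block_lines else "")


def _under(parent_map: dict[str, str], node: str, ancestor: str) -> bool:
    while node in parent_map:
        node = parent_map[node]
        if node == ancestor:
            return True
    return False


def _make_mapping(
    spec: FixtureSpec, pools: dict[int, list[str]], live_terms: dict[str, str]
) -> tuple[str, str]:
    rng = _rng(spec.seed, _OFF_MAP)
    terms = sorted(live_terms)
    map_lines = ["! synthetic external2go mapping", "! generated by goannot fixtures"]
    externals = [f"InterPro:IPR{i:06d}" for i in range(1, 11)]
    for ext in externals:
        for term in rng.sample(terms, k=1 + (rng.random() < 0.3)):
            map_lines.append(
                f"{ext} Synthetic domain {ext[-3:]} > GO:synthetic ; {term}"
            )
    feat_lines = []
    taxon = spec.target_taxon
    for gene in rng.sample(pools[taxon], k=min(40, len(pools[taxon]))):
        for ext in rng.sample(externals, k=rng.randrange(1, 4)):
            feat_lines.append(f"{_db(taxon)}\t{gene}\tsym_{gene}\t{taxon}\t{ext}")
    return "\n".join(map_lines) + "\n", "\n".join(feat_lines) + "\n"


def _make_slim(spec: FixtureSpec, live_terms: dict[str, str]) -> str:
    rng = _rng(spec.seed, _OFF_SLIM)
    picks = rng.sample(sorted(live_terms), k=min(5, len(live_terms)))
    return "# synthetic GO slim\n" + "\n".join(sorted(picks)) + "\n"


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate the full bundle for one spec; byte-deterministic per seed."""
    spec.validate()
    pools = _gene_pools(spec)
    obo, live_terms, obsolete = _make_obo(spec)
    homologene, classes, n_m2m = _make_orthology(spec, pools)
    gaf_records, _ = _make_annotations(spec, pools, live_terms)
    newick_text, assertions_tsv, blocks_tsv = _make_tree(spec, pools, live_terms, gaf_records)
    mapping, features = _make_mapping(spec, pools, live_terms)
    slim = _make_slim(spec, live_terms)
    gaf_by_taxon = {t: _gaf_text(spec, recs) for t, recs in gaf_records.items()}
    return FixtureBundle(
        obo=obo,
        homologene=homologene,
        gaf_by_taxon=gaf_by_taxon,
        newick=newick_text,
        assertions_tsv=assertions_tsv,
        blocks_tsv=blocks_tsv,
        mapping=mapping,
        features_tsv=features,
        slim=slim,
        meta={
            "n_many_to_many": n_m2m,
            "n_classes": len(classes),
            "obsolete_terms": obsolete,
            "live_terms": len(live_terms),
        },
    )
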