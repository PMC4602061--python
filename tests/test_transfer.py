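"""The ISO transfer rule cascade, its report, and the reverse export."""

import io

import pytest

import goannot
from goannot.errors import UsageError
from goannot.fixtures import FixtureSpec, generate_fixture
from goannot.gaf_io import GafDocument, read_gaf
from goannot.orthology import read_homologene
from goannot.transfer import (
    blocked_terms,
    evaluate,
    reverse_export,
    run_transfer,
)

from conftest import make_config
from oracles import annotation_tuple, transfer_oracle

RUN_DATE = "20150601"

MINI_OBO = """format-version: 1.2

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0005515
name: protein binding
namespace: molecular_function
is_a: GO:0003674

[Term]
id: GO:0000010
name: some activity
namespace: molecular_function
is_a: GO:0003674

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0000020
name: some process
namespace: biological_process
is_a: GO:0008150
"""

# class 1 is many-to-many (two mouse genes); class 2 is one-to-one
MINI_HOMOLOGENE = (
    "1\t9606\th1\tH1\n1\t10090\tg1\tG1\n1\t10090\tg2\tG2\n"
    "2\t9606\th2\tH2\n2\t10090\tg3\tG3\n"
)


def human_annotation(gene, go_id, evidence="IDA", aspect="F", qualifiers=()):
    return goannot.Annotation(
        db="UniProtKB",
        db_object_id=gene,
        db_object_symbol=gene.upper(),
        qualifiers=list(qualifiers),
        go_id=go_id,
        references=["PMID:100"],
        evidence_code=evidence,
        with_from=[],
        aspect=aspect,
        db_object_type="gene",
        taxon=["taxon:9606"],
        date="20140101",
        assigned_by="UniProt",
    )


@pytest.fixture(scope="module")
def mini_ontology():
    return goannot.parse_obo(io.StringIO(MINI_OBO))


@pytest.fixture(scope="module")
def mini_ortho():
    return read_homologene(io.StringIO(MINI_HOMOLOGENE))


def decide(ann, mini_ortho, mini_ontology, **config_overrides):
    return evaluate(
        ann,
        mini_ortho,
        mini_ontology,
        make_config(**config_overrides),
        run_date=RUN_DATE,
    )


def test_electronic_evidence_rejected(mini_ortho, mini_ontology):
    d = decide(human_annotation("h2", "GO:0000010", evidence="IEA"), mini_ortho, mini_ontology)
    assert (d.outcome, d.reason) == ("rejected", "not_experimental")


def test_protein_binding_rejected(mini_ortho, mini_ontology):
    d = decide(human_annotation("h2", "GO:0005515"), mini_ortho, mini_ontology)
    assert (d.outcome, d.reason) == ("rejected", "protein_binding")


def test_not_qualifier_rejected(mini_ortho, mini_ontology):
    ann = human_annotation("h2", "GO:0000010", qualifiers=["NOT", "enables"])
    d = decide(ann, mini_ortho, mini_ontology)
    assert (d.outcome, d.reason) == ("rejected", "not_qualifier")


def test_bp_blocked_in_many_to_many_but_mf_fans_out(mini_ortho, mini_ontology):
    bp = human_annotation("h1", "GO:0000020", aspect="P")
    d = decide(bp, mini_ortho, mini_ontology)
    assert (d.outcome, d.reason) == ("rejected", "bp_in_many_to_many")
    mf = human_annotation("h1", "GO:0000010", aspect="F")
    d = decide(mf, mini_ortho, mini_ontology)
    assert d.outcome == "accepted"
    assert sorted(a.db_object_id for a in d.produced) == ["g1", "g2"]


def test_one_to_one_iso_production(mini_ortho, mini_ontology):
    d = decide(human_annotation("h2", "GO:0000010"), mini_ortho, mini_ontology)
    assert d.outcome == "accepted" and len(d.produced) == 1
    iso = d.produced[0]
    assert iso.evidence_code == "ISO"
    assert iso.with_from == ["UniProtKB:h2"]
    assert iso.references == ["GO_REF:0000096"]
    assert iso.db_object_id == "g3"
    assert iso.taxon == ["taxon:10090"]
    assert iso.assigned_by == "goannot-test"
    assert iso.date == RUN_DATE


def test_unclassified_and_partnerless_reasons(mini_ontology):
    ortho = read_homologene(io.StringIO("9\t9606\th5\tH5\n9\t10116\tr5\tR5\n"))
    d = decide(human_annotation("h9", "GO:0000010"), ortho, mini_ontology)
    assert d.reason == "no_orthology_class"
    d = decide(human_annotation("h5", "GO:0000010"), ortho, mini_ontology)
    assert d.reason == "no_target_partner"


def test_taxon_mismatch_is_usage_error(mini_ortho, mini_ontology):
    rat = human_annotation("h2", "GO:0000010")
    rat.taxon = ["taxon:10116"]
    with pytest.raises(UsageError):
        decide(rat, mini_ortho, mini_ontology)


def test_class_wide_not_blocking(mini_ortho, mini_ontology):
    # a NOT annotation on the *mouse* member blocks the human->mouse transfer
    mouse_not = goannot.Annotation(
        db="MGI",
        db_object_id="g3",
        db_object_symbol="G3",
        qualifiers=["NOT", "enables"],
        go_id="GO:0000010",
        references=["PMID:7"],
        evidence_code="IDA",
        with_from=[],
        aspect="F",
        taxon=["taxon:10090"],
        date="20140101",
        assigned_by="MGI",
    )
    cls = mini_ortho.classes["2"]
    blocked = blocked_terms(cls, [mouse_not])
    assert blocked == {"GO:0000010"}
    d = evaluate(
        human_annotation("h2", "GO:0000010"),
        mini_ortho,
        mini_ontology,
        make_config(),
        blocked={"2": blocked},
        run_date=RUN_DATE,
    )
    assert (d.outcome, d.reason) == ("rejected", "class_not_blocked_but_term_notted")


def test_duplicate_suppression(mini_ortho, mini_ontology):
    existing = goannot.Annotation(
        db="MGI",
        db_object_id="g3",
        db_object_symbol="G3",
        qualifiers=[],
        go_id="GO:0000010",
        references=["PMID:8"],
        evidence_code="IMP",
        with_from=[],
        aspect="F",
        taxon=["taxon:10090"],
        date="20140101",
        assigned_by="MGI",
    )
    d = evaluate(
        human_annotation("h2", "GO:0000010"),
        mini_ortho,
        mini_ontology,
        make_config(),
        target_annotations=[existing],
        run_date=RUN_DATE,
    )
    assert (d.outcome, d.reason) == ("rejected", "duplicate_of_experimental")
    d = evaluate(
        human_annotation("h2", "GO:0000010"),
        mini_ortho,
        mini_ontology,
        make_config(suppress_if_experimental_duplicate=False),
        target_annotations=[existing],
        run_date=RUN_DATE,
    )
    assert d.outcome == "accepted"


def test_worked_document_run(mini_ortho, mini_ontology):
    """The worked example set: 3 ISO records out, reasons fully accounted."""
    source = GafDocument(
        version="2.2",
        header_lines=["!gaf-version: 2.2"],
        annotations=[
            human_annotation("h2", "GO:0000010", evidence="IEA"),
            human_annotation("h2", "GO:0005515"),
            human_annotation("h1", "GO:0000020", aspect="P"),
            human_annotation("h1", "GO:0000010", aspect="F"),
            # NOT record targets a term nothing else transfers, so its
            # class-wide block has no side effect on the other examples
            human_annotation("h2", "GO:0000020", aspect="P", qualifiers=["NOT", "involved_in"]),
            human_annotation("h2", "GO:0000010"),
        ],
    )
    target = GafDocument(version="2.2", header_lines=["!gaf-version: 2.2"])
    out, report, decisions = run_transfer(
        source, target, mini_ortho, mini_ontology, make_config(), run_date=RUN_DATE
    )
    assert len(out) == 3
    assert dict(report.reason_counts) == {
        "not_experimental": 1,
        "protein_binding": 1,
        "bp_in_many_to_many": 1,
        "not_qualifier": 1,
        "ok": 2,
    }
    assert report.evaluated == 6 == sum(report.reason_counts.values())
    assert report.produced_total == 3


def test_empty_source_document(mini_ortho, mini_ontology):
    empty = GafDocument(version="2.2", header_lines=["!gaf-version: 2.2"])
    out, report, _ = run_transfer(
        empty, empty, mini_ortho, mini_ontology, make_config(), run_date=RUN_DATE
    )
    assert len(out) == 0 and report.evaluated == 0 and not report.reason_counts


def run_fixture_transfer(seed, **config_overrides):
    bundle = generate_fixture(FixtureSpec(seed=seed))
    ontology = goannot.parse_obo(io.StringIO(bundle.obo))
    ortho = read_homologene(io.StringIO(bundle.homologene))
    source = read_gaf(io.StringIO(bundle.gaf_by_taxon[9606]))
    target = read_gaf(io.StringIO(bundle.gaf_by_taxon[10090]))
    config = make_config(**config_overrides)
    out, report, decisions = run_transfer(
        source, target, ortho, ontology, config, run_date=RUN_DATE
    )
    return bundle, out, report, decisions


@pytest.mark.parametrize("seed", [1, 4, 7])
def test_fixture_run_matches_brute_force_oracle(seed):
    bundle, out, report, _ = run_fixture_transfer(seed)
    expected, reasons = transfer_oracle(
        bundle.gaf_by_taxon[9606],
        bundle.gaf_by_taxon[10090],
        bundle.homologene,
        source_taxon=9606,
        target_taxon=10090,
        load_reference="GO_REF:0000096",
        assigned_by="goannot-test",
        target_db="MGI",
        run_date=RUN_DATE,
    )
    assert {annotation_tuple(a) for a in out.annotations} == expected
    assert dict(report.reason_counts) == dict(reasons)


def test_anti_circularity_on_fixture():
    bundle, out, report, _ = run_fixture_transfer(4)
    ontology = goannot.parse_obo(io.StringIO(bundle.obo))
    ortho = read_homologene(io.StringIO(bundle.homologene))
    source = read_gaf(io.StringIO(bundle.gaf_by_taxon[9606]))
    target = read_gaf(io.StringIO(bundle.gaf_by_taxon[10090]))
    source.annotations.extend(a.copy() for a in out.annotations)
    out2, report2, _ = run_transfer(
        source, target, ortho, ontology, make_config(), run_date=RUN_DATE
    )
    assert {annotation_tuple(a) for a in out2.annotations} == {
        annotation_tuple(a) for a in out.annotations
    }
    assert report2.reason_counts["not_experimental"] == report.reason_counts.get(
        "not_experimental", 0
    ) + len(out)


def test_produced_records_respect_safety_invariants():
    bundle, out, _, _ = run_fixture_transfer(5)
    ortho = read_homologene(io.StringIO(bundle.homologene))
    source = read_gaf(io.StringIO(bundle.gaf_by_taxon[9606]))
    target = read_gaf(io.StringIO(bundle.gaf_by_taxon[10090]))
    pool = source.annotations + target.annotations
    for ann in out.annotations:
        assert not ann.is_not
        assert ann.go_id != "GO:0005515"
        cls = ortho.class_of(10090, ann.db_object_id)
        assert cls is not None
        if ann.aspect == "P":
            from goannot.orthology import is_many_to_many

            assert not is_many_to_many(cls)
        assert ann.go_id not in blocked_terms(cls, pool)


def test_report_conservation():
    _, out, report, decisions = run_fixture_transfer(6)
    assert report.evaluated == len(decisions) == sum(report.reason_counts.values())
    accepted_targets = sum(len(d.produced) for d in decisions)
    assert report.produced_total <= accepted_targets
    assert report.produced_total == len(out)


def test_reverse_export_celf4_pattern():
    """A curated mouse ISO record becomes an experimental record of its
    human with/from gene, citing the original publication."""
    curated = GafDocument(
        version="2.2",
        header_lines=["!gaf-version: 2.2"],
        annotations=[
            goannot.Annotation(
                db="MGI",
                db_object_id="MGI:1344411",
                db_object_symbol="Celf4",
                qualifiers=["enables"],
                go_id="GO:0000010",
                references=["GO_REF:0000008"],
                evidence_code="ISO",
                with_from=["UniProtKB:Q9BZC1"],
                aspect="F",
                taxon=["taxon:10090"],
                date="20140101",
                assigned_by="MGI",
            ),
            goannot.Annotation(
                db="MGI",
                db_object_id="MGI:2",
                db_object_symbol="Other",
                qualifiers=[],
                go_id="GO:0000010",
                references=["GO_REF:0000002"],
                evidence_code="IEA",
                with_from=["InterPro:IPR000001"],
                aspect="F",
                taxon=["taxon:10090"],
                date="20140101",
                assigned_by="MGI",
            ),
        ],
    )
    evidence_map = {("MGI", "MGI:1344411", "GO:0000010"): ("IDA", "PMID:11158314")}
    taxon_map = {"UniProtKB:Q9BZC1": 9606}
    out = reverse_export(curated, evidence_map, taxon_map)
    assert len(out) == 1  # the IEA record is ineligible and skipped
    rec = out.annotations[0]
    assert (rec.db, rec.db_object_id) == ("UniProtKB", "Q9BZC1")
    assert rec.evidence_code == "IDA"
    assert rec.references == ["PMID:11158314"]
    assert rec.with_from == []
    assert rec.taxon == ["taxon:9606"]


def test_reverse_export_recovers_transfer_sources():
    """Composition: transfer then reverse export returns the source genes."""
    _, out, _, _ = run_fixture_transfer(3)
    evidence_map = {
        (a.db, a.db_object_id, a.go_id): ("IDA", "PMID:1") for a in out.annotations
    }
    taxon_map = {a.with_from[0]: 9606 for a in out.annotations}
    back = reverse_export(out, evidence_map, taxon_map)
    assert len(back) == len(out)
    original_subjects = {a.with_from[0] for a in out.annotations}
    assert {f"{a.db}:{a.db_object_id}" for a in back.annotations} <= original_subjects
    for fwd, rev in zip(out.annotations, back.annotations):
        assert f"{rev.db}:{rev.db_object_id}" == fwd.with_from[0]
        assert rev.go_id == fwd.go_id
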