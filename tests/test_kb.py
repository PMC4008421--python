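"""Knowledge-base loading, validation and exhaustive consistency checking."""

import json
import random

import pytest

from medsafecode.errors import CapacityError, KBLoadError, KBReferenceError
from medsafecode.kb import (
    And,
    CDSRule,
    FindingCategory,
    HaplotypeDefinition,
    HasExactly,
    HasSome,
    KnowledgeBase,
    MarkerDefinition,
    VariantAtom,
    check_consistency,
    condition_from_obj,
    condition_to_obj,
    kb_to_dict,
    load_kb,
    parse_kb,
    satisfiable,
    save_kb,
)

from oracles import oracle_findings, random_kb


def test_fixture_kb_roundtrips_through_file(paper_kb, tmp_path):
    path = save_kb(paper_kb, tmp_path / "kb.json")
    kb = load_kb(path)
    assert kb.haplotype_map.keys() == {"CYP2C9*1", "CYP2C9*3"}
    assert [r.rule_id for r in kb.rules] == ["rule9"]
    assert kb.panel == ("rs1057910", "rs1057911", "rs1799853", "rs2256871", "rs9923231")
    assert kb == paper_kb


def test_empty_panel_kb_is_valid():
    kb = parse_kb({"version": "v0.2", "build": "GRCh37", "markers": [], "haplotypes": [], "rules": []})
    assert kb.markers == () and kb.haplotypes == () and kb.rules == ()
    assert check_consistency(kb) == []


def test_dangling_marker_reference_names_the_rsid(paper_kb, tmp_path):
    doc = kb_to_dict(paper_kb)
    doc["rules"][0]["condition"]["and"].append({"has_some": "rs999_A"})
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(KBReferenceError, match="rs999"):
        load_kb(path)


@pytest.mark.parametrize(
    "mutate, match",
    [
        (lambda d: d["markers"][0].update(reference="C"), "reference nucleotide"),
        (lambda d: d["markers"].append(dict(d["markers"][0])), "duplicate rsid"),
        (lambda d: d["markers"][0].update(allowed=["A", "A"]), "duplicate allowed"),
        (lambda d: d["markers"][0].update(chromosome="99"), "bad chromosome"),
        (lambda d: d["haplotypes"][0].update(sufficient=[]), "non-empty"),
        (lambda d: d["rules"][0].update(message=""), "message"),
        (
            lambda d: d["rules"][0].update(condition={"or": [{"has_some": "rs1057910_C"}]}),
            "unsupported condition construct",
        ),
        (
            lambda d: d["rules"][0].update(
                condition={"has_exactly": {"n": 3, "atom": "rs9923231_T"}}
            ),
            "0..2",
        ),
    ],
)
def test_schema_violations_name_the_offending_record(paper_kb, tmp_path, mutate, match):
    doc = kb_to_dict(paper_kb)
    mutate(doc)
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(KBLoadError, match=match):
        load_kb(path)


def test_sufficient_outside_necessary_is_united_with_warning(paper_kb, tmp_path, caplog):
    doc = kb_to_dict(paper_kb)
    star1 = doc["haplotypes"][0]
    assert star1["label"] == "*1"
    star1["necessary"] = []  # drop containment; loader must repair
    path = tmp_path / "kb.json"
    path.write_text(json.dumps(doc))
    with caplog.at_level("WARNING", logger="medsafecode.kb"):
        kb = load_kb(path)
    assert "uniting" in caplog.text
    hap = kb.haplotype_map["CYP2C9*1"]
    assert hap.sufficient <= hap.necessary


def test_condition_serialization_roundtrip(paper_kb):
    cond = paper_kb.rules[0].condition
    obj = condition_to_obj(cond)
    assert obj == {
        "and": [
            {"has_haplotype": "CYP2C9*1"},
            {"has_haplotype": "CYP2C9*3"},
            {"has_exactly": {"n": 2, "atom": "rs9923231_T"}},
        ]
    }
    assert condition_from_obj(obj, "test") == cond


# ---------------------------------------------------------------------------
# Satisfiability


def test_satisfiable_single_atom_returns_evaluating_witness(paper_kb):
    sat, witness = satisfiable(HasSome(VariantAtom("rs1057910", "C")), paper_kb)
    assert sat and "C" in witness["rs1057910"]


def test_satisfiable_homozygous_cardinality_witness(paper_kb):
    sat, witness = satisfiable(HasExactly(2, VariantAtom("rs9923231", "T")), paper_kb)
    assert sat and witness["rs9923231"] == ("T", "T")


def test_contradictory_cardinality_is_unsatisfiable(paper_kb):
    cond = And(
        (
            HasExactly(0, VariantAtom("rs1057910", "C")),
            HasSome(VariantAtom("rs1057910", "C")),
        )
    )
    sat, witness = satisfiable(cond, paper_kb)
    assert not sat and witness is None


def test_capacity_bound_raises_naming_entity(paper_kb):
    cond = And(tuple(HasSome(VariantAtom(m.rsid, m.reference)) for m in paper_kb.markers))
    with pytest.raises(CapacityError, match="references 5 markers"):
        satisfiable(cond, paper_kb, max_markers=4, entity="rule X")


# ---------------------------------------------------------------------------
# Consistency checking


def test_fixture_kb_has_no_findings(paper_kb):
    assert check_consistency(paper_kb) == []


def _one_marker_kb(allowed=("A", "C")):
    return KnowledgeBase(
        "vtest", "synthetic",
        (MarkerDefinition("rs1", "1", 100, allowed[0], tuple(allowed)),),
        (), (),
    )


def test_impossible_necessary_atom_is_flagged_tag_not_entailing():
    base = _one_marker_kb()
    markers = base.markers + (MarkerDefinition("rs2", "1", 200, "G", ("G", "T")),)
    hap = HaplotypeDefinition(
        "G1", "*1",
        frozenset({VariantAtom("rs1", "A")}),
        frozenset({VariantAtom("rs1", "A"), VariantAtom("rs2", "C")}),  # C unobservable
    )
    kb = KnowledgeBase("vtest", "synthetic", markers, (hap,), ())
    findings = check_consistency(kb)
    assert [(f.category, f.entity_id) for f in findings] == [
        (FindingCategory.TAG_NOT_ENTAILING, "G1*1")
    ]


def test_entailment_style_necessary_atoms_are_not_flagged(paper_kb):
    # the *3 definition's necessary atoms live on independent markers: the
    # tag can co-occur with each of them, so the definition is clean even
    # though the tag does not logically force them
    hap = paper_kb.haplotype_map["CYP2C9*3"]
    assert len(hap.necessary - hap.sufficient) == 3
    assert check_consistency(paper_kb) == []


def test_overfull_cardinality_rule_is_flagged_unsatisfiable():
    base = _one_marker_kb()
    rule = CDSRule(
        "bad",
        And((HasExactly(2, VariantAtom("rs1", "A")), HasExactly(2, VariantAtom("rs1", "C")))),
        "impossible",
    )
    kb = KnowledgeBase("vtest", "synthetic", base.markers, (), (rule,))
    findings = check_consistency(kb)
    assert [(f.category, f.entity_id) for f in findings] == [
        (FindingCategory.UNSATISFIABLE_RULE, "bad")
    ]


def test_duplicate_tag_sets_within_a_gene_are_flagged():
    base = _one_marker_kb()
    atoms = frozenset({VariantAtom("rs1", "C")})
    haps = (
        HaplotypeDefinition("G1", "*2", atoms, atoms),
        HaplotypeDefinition("G1", "*3", atoms, atoms),
        HaplotypeDefinition("G2", "*2", atoms, atoms),  # other gene: allowed
    )
    kb = KnowledgeBase("vtest", "synthetic", base.markers, haps, ())
    findings = check_consistency(kb)
    assert [(f.category, f.entity_id) for f in findings] == [
        (FindingCategory.DUPLICATE_DEFINITION, "G1*2==G1*3")
    ]


def test_unsatisfiable_haplotype_three_nucleotide_tag_set():
    kb = _one_marker_kb(allowed=("A", "C", "G"))
    hap = HaplotypeDefinition(
        "G1", "*1",
        frozenset({VariantAtom("rs1", "A"), VariantAtom("rs1", "C"), VariantAtom("rs1", "G")}),
        frozenset({VariantAtom("rs1", "A"), VariantAtom("rs1", "C"), VariantAtom("rs1", "G")}),
    )
    kb = KnowledgeBase("vtest", "synthetic", kb.markers, (hap,), ())
    findings = check_consistency(kb)
    assert [(f.category, f.entity_id) for f in findings] == [
        (FindingCategory.UNSATISFIABLE_HAPLOTYPE, "G1*1")
    ]


def test_rule_exceeding_marker_bound_raises_never_skips():
    markers = tuple(
        MarkerDefinition(f"rs{i}", "1", 100 + i, "A", ("A", "C")) for i in range(1, 5)
    )
    rule = CDSRule(
        "wide",
        And(tuple(HasSome(VariantAtom(m.rsid, "A")) for m in markers)),
        "wide rule",
    )
    kb = KnowledgeBase("vtest", "synthetic", markers, (), (rule,))
    with pytest.raises(CapacityError, match="rule wide"):
        check_consistency(kb, max_markers_per_check=3)


def test_findings_are_deterministic_and_sorted():
    base = _one_marker_kb()
    atoms = frozenset({VariantAtom("rs1", "C")})
    haps = (
        HaplotypeDefinition("G1", "*3", atoms, atoms),
        HaplotypeDefinition("G1", "*2", atoms, atoms),
    )
    rule = CDSRule(
        "zz",
        And((HasExactly(2, VariantAtom("rs1", "A")), HasExactly(2, VariantAtom("rs1", "C")))),
        "impossible",
    )
    kb = KnowledgeBase("vtest", "synthetic", base.markers, haps, (rule,))
    first = check_consistency(kb)
    second = check_consistency(kb)
    assert first == second
    assert [f.category.value for f in first] == sorted(f.category.value for f in first)


def test_consistency_agrees_with_bruteforce_on_random_kbs():
    rng = random.Random(1729)
    for _ in range(60):
        kb = random_kb(rng)
        got = {(f.category.value, f.entity_id) for f in check_consistency(kb)}
        assert got == oracle_findings(kb)


def test_satisfiable_agrees_with_bruteforce_on_random_rules():
    from oracles import holds, oracle_satisfiable

    rng = random.Random(271828)
    for _ in range(60):
        kb = random_kb(rng)
        for rule in kb.rules:
            sat, witness = satisfiable(rule.condition, kb)
            assert sat == oracle_satisfiable(rule.condition, kb)
            if sat:
                # returned witness must itself satisfy the condition
                full = dict(witness)
                for m in kb.markers:  # pad unreferenced markers arbitrarily
                    full.setdefault(m.rsid, (m.reference, m.reference))
                assert holds(rule.condition, full, kb)
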