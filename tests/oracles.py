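"""Independent brute-force oracles for property and acceptance tests.

Everything here re-derives results by direct enumeration, sharing only the
knowledge-base *data types* with the package — never its evaluation,
satisfiability or consistency-checking code paths.
"""

from __future__ import annotations

import random
from typing import Iterator, Optional

from medsafecode.genotype_io import UNKNOWN, GenotypeProfile
from medsafecode.kb import (
    And,
    CDSRule,
    ConditionExpr,
    HaplotypeDefinition,
    HasExactly,
    HasHaplotype,
    HasSome,
    KnowledgeBase,
    MarkerDefinition,
    VariantAtom,
)


def pairs_of(marker: MarkerDefinition) -> list[tuple[str, str]]:
    alleles = sorted(marker.allowed)
    return [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]


def all_genotypes(kb: KnowledgeBase) -> Iterator[dict[str, tuple[str, str]]]:
    """Every complete diploid genotype over ALL markers of the KB."""
    markers = list(kb.markers)

    def rec(i: int, acc: dict) -> Iterator[dict]:
        if i == len(markers):
            yield dict(acc)
            return
        for pair in pairs_of(markers[i]):
            acc[markers[i].rsid] = pair
            yield from rec(i + 1, acc)

    yield from rec(0, {})


def holds(cond: ConditionExpr, genotype: dict[str, tuple[str, str]], kb: KnowledgeBase) -> bool:
    """Direct two-valued evaluation on a complete genotype."""
    if isinstance(cond, HasSome):
        pair = genotype[cond.atom.rsid]
        return pair[0] == cond.atom.nucleotide or pair[1] == cond.atom.nucleotide
    if isinstance(cond, HasExactly):
        pair = genotype[cond.atom.rsid]
        n = (1 if pair[0] == cond.atom.nucleotide else 0) + (
            1 if pair[1] == cond.atom.nucleotide else 0
        )
        return n == cond.n
    if isinstance(cond, HasHaplotype):
        hap = next(h for h in kb.haplotypes if h.gene == cond.gene and h.label == cond.label)
        return all(
            holds(HasSome(a), genotype, kb) for a in hap.sufficient
        )
    if isinstance(cond, And):
        return all(holds(c, genotype, kb) for c in cond.children)
    raise TypeError(cond)


def oracle_satisfiable(cond: ConditionExpr, kb: KnowledgeBase) -> bool:
    return any(holds(cond, g, kb) for g in all_genotypes(kb))


def oracle_findings(kb: KnowledgeBase) -> set[tuple[str, str]]:
    """(category, entity_id) pairs from a from-scratch genotype-space loop."""
    out: set[tuple[str, str]] = set()
    for i, h1 in enumerate(kb.haplotypes):
        for h2 in kb.haplotypes[i + 1 :]:
            if h1.gene == h2.gene and h1.sufficient == h2.sufficient:
                out.add(("DUPLICATE_DEFINITION", "==".join(sorted([h1.name, h2.name]))))
    for hap in kb.haplotypes:
        suff = And(tuple(HasSome(a) for a in sorted(hap.sufficient, key=str)))
        if not oracle_satisfiable(suff, kb):
            out.add(("UNSATISFIABLE_HAPLOTYPE", hap.name))
            continue
        for atom in hap.necessary - hap.sufficient:
            if not oracle_satisfiable(And(suff.children + (HasSome(atom),)), kb):
                out.add(("TAG_NOT_ENTAILING", hap.name))
    for rule in kb.rules:
        if not oracle_satisfiable(rule.condition, kb):
            out.add(("UNSATISFIABLE_RULE", rule.rule_id))
    return out


def completions(profile: GenotypeProfile, kb: KnowledgeBase) -> Iterator[dict]:
    """All complete genotypes agreeing with the profile's known calls."""
    markers = list(kb.markers)

    def rec(i: int, acc: dict) -> Iterator[dict]:
        if i == len(markers):
            yield dict(acc)
            return
        rsid = markers[i].rsid
        call = profile.calls.get(rsid, UNKNOWN)
        options = [call] if call is not UNKNOWN else pairs_of(markers[i])
        for pair in options:
            acc[rsid] = pair
            yield from rec(i + 1, acc)

    yield from rec(0, {})


def oracle_status(cond: ConditionExpr, profile: GenotypeProfile, kb: KnowledgeBase) -> str:
    """Supervaluation status: TRUE iff true under every completion, FALSE iff
    false under every completion, else UNKNOWN."""
    seen_true = seen_false = False
    for genotype in completions(profile, kb):
        if holds(cond, genotype, kb):
            seen_true = True
        else:
            seen_false = True
        if seen_true and seen_false:
            return "UNKNOWN"
    return "TRUE" if seen_true else "FALSE"


# ---------------------------------------------------------------------------
# Random small KBs / profiles for the oracle-agreement suites


def random_atom(rng: random.Random, markers: list[MarkerDefinition]) -> VariantAtom:
    m = rng.choice(markers)
    return VariantAtom(m.rsid, rng.choice(m.allowed))


def random_kb(rng: random.Random) -> KnowledgeBase:
    n = rng.randint(1, 6)
    markers = []
    for i in range(n):
        k = rng.choice([2, 2, 2, 3])
        alleles = rng.sample("ACGT", k)
        markers.append(
            MarkerDefinition(f"rs{i + 1}", str(rng.randint(1, 22)), 1000 + i, alleles[0], tuple(alleles))
        )
    haplotypes = []
    for j in range(rng.randint(0, 3)):
        suff = frozenset(random_atom(rng, markers) for _ in range(rng.randint(1, 2)))
        extra = frozenset(random_atom(rng, markers) for _ in range(rng.randint(0, 1)))
        haplotypes.append(HaplotypeDefinition(f"G{j + 1}", "*1", suff, suff | extra))
    rules = []
    for j in range(rng.randint(1, 3)):
        children: list[ConditionExpr] = []
        for _ in range(rng.randint(1, 3)):
            t = rng.random()
            if t < 0.40:
                children.append(HasSome(random_atom(rng, markers)))
            elif t < 0.75:
                children.append(HasExactly(rng.randint(0, 2), random_atom(rng, markers)))
            elif haplotypes:
                hap = rng.choice(haplotypes)
                children.append(HasHaplotype(hap.gene, hap.label))
            else:
                children.append(HasSome(random_atom(rng, markers)))
        rules.append(CDSRule(f"r{j + 1}", And(tuple(children)), f"message {j + 1}"))
    return KnowledgeBase(
        version="vtest",
        build="synthetic",
        markers=tuple(markers),
        haplotypes=tuple(haplotypes),
        rules=tuple(rules),
    )


def random_partial_profile(
    rng: random.Random, kb: KnowledgeBase, known_prob: float = 0.6
) -> GenotypeProfile:
    calls: dict[str, Optional[tuple[str, str]]] = {}
    for marker in kb.markers:
        if rng.random() < known_prob:
            calls[marker.rsid] = rng.choice(pairs_of(marker))
        else:
            calls[marker.rsid] = UNKNOWN
    return GenotypeProfile(calls=calls, source_format="manual")


def inject_unsatisfiable_rule(kb: KnowledgeBase, rng: random.Random) -> KnowledgeBase:
    """Add a rule demanding 2 copies of each of two different nucleotides."""
    m = rng.choice(kb.markers)
    cond = And(
        (
            HasExactly(2, VariantAtom(m.rsid, m.allowed[0])),
            HasExactly(2, VariantAtom(m.rsid, m.allowed[1])),
        )
    )
    rule = CDSRule("inj_unsat", cond, "injected defect")
    return KnowledgeBase(
        kb.version, kb.build, kb.markers, kb.haplotypes, kb.rules + (rule,), kb.panel_genes
    )


def inject_non_entailing_tag(kb: KnowledgeBase, rng: random.Random) -> KnowledgeBase:
    """Add a haplotype whose necessary atom names a nucleotide the marker
    can never carry (constructed in memory; file loading would reject it)."""
    m = rng.choice(kb.markers)
    impossible = next(b for b in "ACGT" if b not in m.allowed)
    tag = VariantAtom(m.rsid, m.allowed[0])
    hap = HaplotypeDefinition(
        "INJGENE",
        "*9",
        frozenset({tag}),
        frozenset({tag, VariantAtom(m.rsid, impossible)}),
    )
    return KnowledgeBase(
        kb.version, kb.build, kb.markers, kb.haplotypes + (hap,), kb.rules, kb.panel_genes
    )
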