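"""Three-valued interpretation of a genotype profile against the KB.

Replaces description-logic realization with rule evaluation under a
true/false/unknown semantics.  A condition atom over a marker whose
genotype is UNKNOWN evaluates to UNKNOWN; conjunction follows strong Kleene
logic (FALSE dominates, all-TRUE gives TRUE, otherwise UNKNOWN).  This
preserves the clinically relevant distinction between "rule does not apply"
and "cannot tell from the available markers".

Kleene conjunction alone is sound but can leave a condition UNKNOWN that is
in fact false under *every* way of filling in the missing genotypes (for
example two incompatible cardinality atoms on one marker).  Statuses are
therefore refined against the completion semantics: a Kleene-UNKNOWN
condition whose unknown markers admit no satisfying completion is reported
FALSE.  The resulting status is exactly TRUE / FALSE / UNKNOWN according to
whether the condition holds under all / no / some-but-not-all completions.
(TRUE under all completions while a referenced marker is unknown is
impossible in this conjunctive fragment, so no TRUE-refinement is needed.)
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import EvaluationError
from .genotype_io import UNKNOWN, GenotypeProfile, restrict_to_panel
from .kb import (
    And,
    ConditionExpr,
    HasExactly,
    HasHaplotype,
    HasSome,
    KnowledgeBase,
    VariantAtom,
    eval_complete,
    expand_condition,
    referenced_markers,
)


class TruthValue(Enum):
    TRUE = "TRUE"
    FALSE = "FALSE"
    UNKNOWN = "UNKNOWN"


def kleene_and(values: "list[TruthValue] | tuple[TruthValue, ...]") -> TruthValue:
    if any(v is TruthValue.FALSE for v in values):
        return TruthValue.FALSE
    if all(v is TruthValue.TRUE for v in values):
        return TruthValue.TRUE
    return TruthValue.UNKNOWN


def evaluate_atom(
    profile: GenotypeProfile,
    atom: VariantAtom,
    exactly: Optional[int] = None,
) -> TruthValue:
    """Evaluate ``has some atom`` (or ``has exactly n atom`` when given).

    UNKNOWN genotype propagates to UNKNOWN; otherwise the nucleotide count
    in the diploid pair decides.
    """
    if atom.rsid not in profile.calls:
        raise EvaluationError(f"atom references marker {atom.rsid} absent from the profile panel")
    call = profile.calls[atom.rsid]
    if call is UNKNOWN:
        return TruthValue.UNKNOWN
    count = call.count(atom.nucleotide)
    if exactly is None:
        return TruthValue.TRUE if count >= 1 else TruthValue.FALSE
    return TruthValue.TRUE if count == exactly else TruthValue.FALSE


def _kleene_eval(cond: ConditionExpr, profile: GenotypeProfile, kb: KnowledgeBase) -> TruthValue:
    if isinstance(cond, HasSome):
        return evaluate_atom(profile, cond.atom)
    if isinstance(cond, HasExactly):
        return evaluate_atom(profile, cond.atom, exactly=cond.n)
    if isinstance(cond, HasHaplotype):
        return _kleene_eval(expand_condition(cond, kb), profile, kb)
    if isinstance(cond, And):
        return kleene_and([_kleene_eval(c, profile, kb) for c in cond.children])
    raise TypeError(f"not a condition: {cond!r}")


_REFINEMENT_CAP = 12  # markers; beyond this an UNKNOWN status is left as-is


def evaluate_condition(
    cond: ConditionExpr, profile: GenotypeProfile, kb: KnowledgeBase
) -> TruthValue:
    """Exact three-valued status of a condition over a (partial) profile."""
    status = _kleene_eval(cond, profile, kb)
    if status is not TruthValue.UNKNOWN:
        return status
    expanded = expand_condition(cond, kb)
    rsids = sorted(referenced_markers(cond, kb))
    unknown = [r for r in rsids if profile.calls.get(r) is UNKNOWN]
    if not unknown or len(unknown) > _REFINEMENT_CAP:
        return TruthValue.UNKNOWN
    fixed = {r: profile.calls[r] for r in rsids if profile.calls.get(r) is not UNKNOWN}
    marker_map = kb.marker_map
    for combo in itertools.product(*[marker_map[r].pairs() for r in unknown]):
        genotype = dict(fixed)
        genotype.update(zip(unknown, combo))
        if eval_complete(expanded, genotype, kb):
            return TruthValue.UNKNOWN  # some completion satisfies it
    return TruthValue.FALSE  # no completion can satisfy it


# ---------------------------------------------------------------------------
# Report types


@dataclass(frozen=True)
class AlleleCall:
    gene: str
    label: str
    status: TruthValue
    conflict: bool = False
    supporting_atoms: tuple[str, ...] = ()

    @property
    def name(self) -> str:
        return f"{self.gene}{self.label}"


@dataclass(frozen=True)
class RuleMatch:
    rule_id: str
    status: TruthValue
    message: str
    missing_markers: tuple[str, ...] = ()


@dataclass(frozen=True)
class InterpretationReport:
    allele_calls: tuple[AlleleCall, ...]
    rule_matches: tuple[RuleMatch, ...]
    known_markers: int
    unknown_markers: int
    kb_version: str

    def triggered(self) -> tuple[RuleMatch, ...]:
        return tuple(r for r in self.rule_matches if r.status is TruthValue.TRUE)

    def to_dict(self) -> dict:
        return {
            "kb_version": self.kb_version,
            "profile_summary": {
                "known_markers": self.known_markers,
                "unknown_markers": self.unknown_markers,
            },
            "allele_calls": [
                {
                    "gene": a.gene,
                    "label": a.label,
                    "status": a.status.value,
                    "conflict": a.conflict,
                    "supporting_atoms": list(a.supporting_atoms),
                }
                for a in self.allele_calls
            ],
            "rule_matches": [
                {
                    "rule_id": r.rule_id,
                    "status": r.status.value,
                    "message": r.message,
                    "missing_markers": list(r.missing_markers),
                }
                for r in self.rule_matches
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def to_text(self) -> str:
        lines = [
            f"Knowledge base version: {self.kb_version}",
            f"Panel markers: {self.known_markers} known, {self.unknown_markers} unknown",
            "",
            "Allele calls:",
        ]
        for a in self.allele_calls:
            flag = "  [CONFLICT: a necessary variant is absent]" if a.conflict else ""
            lines.append(f"  {a.name}: {a.status.value}{flag}")
        lines.append("")
        lines.append("Recommendations:")
        any_rule = False
        for r in self.rule_matches:
            any_rule = True
            if r.status is TruthValue.TRUE:
                lines.append(f"  [{r.rule_id}] TRIGGERED: {r.message}")
            elif r.status is TruthValue.UNKNOWN:
                missing = ", ".join(r.missing_markers)
                lines.append(f"  [{r.rule_id}] INSUFFICIENT DATA (missing: {missing})")
            else:
                lines.append(f"  [{r.rule_id}] not applicable")
        if not any_rule:
            lines.append("  (no rules in knowledge base)")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Realization


def call_haplotypes(profile: GenotypeProfile, kb: KnowledgeBase) -> tuple[AlleleCall, ...]:
    """Status of every star allele in the KB over the profile.

    An allele is TRUE when all its tag (sufficient) variants are present on
    at least one chromosome; unphased data therefore reports *presence*, not
    a phased diplotype, and a compound heterozygote matches both alleles.
    ``conflict`` marks a matching tag set while some necessary variant is
    demonstrably absent — a red flag for the definition or the assay.
    """
    calls = []
    for hap in sorted(kb.haplotypes, key=lambda h: (h.gene, h.label)):
        cond = And(tuple(HasSome(a) for a in sorted(hap.sufficient, key=str)))
        status = evaluate_condition(cond, profile, kb)
        conflict = False
        supporting: tuple[str, ...] = ()
        if status is TruthValue.TRUE:
            supporting = tuple(sorted(str(a) for a in hap.sufficient))
            conflict = any(
                evaluate_atom(profile, a) is TruthValue.FALSE for a in hap.necessary
            )
        calls.append(AlleleCall(hap.gene, hap.label, status, conflict, supporting))
    return tuple(calls)


def match_rules(
    profile: GenotypeProfile,
    calls: tuple[AlleleCall, ...],
    kb: KnowledgeBase,
) -> tuple[RuleMatch, ...]:
    """Evaluate every CDS rule; TRUE rules carry their recommendation.

    Rule conditions are evaluated with haplotype references expanded into
    their tag conjunctions (so joint constraints across alleles sharing a
    marker are honoured); the per-allele statuses in ``calls`` agree with
    this evaluation on every individual haplotype atom.
    """
    matches = []
    for rule in sorted(kb.rules, key=lambda r: r.rule_id):
        status = evaluate_condition(rule.condition, profile, kb)
        missing: tuple[str, ...] = ()
        if status is TruthValue.UNKNOWN:
            missing = tuple(
                sorted(
                    r
                    for r in referenced_markers(rule.condition, kb)
                    if profile.calls.get(r) is UNKNOWN
                )
            )
        matches.append(RuleMatch(rule.rule_id, status, rule.message, missing))
    return tuple(matches)


def interpret(profile: GenotypeProfile, kb: KnowledgeBase) -> InterpretationReport:
    """Full pipeline: panel restriction, allele calls, rule matching.

    A pure function of (profile, kb): repeated calls give byte-identical
    reports (genes alphabetical, rules by rule id).
    """
    panel_profile = restrict_to_panel(profile, kb)
    calls = call_haplotypes(panel_profile, kb)
    matches = match_rules(panel_profile, calls, kb)
    return InterpretationReport(
        allele_calls=calls,
        rule_matches=matches,
        known_markers=panel_profile.known_count(),
        unknown_markers=panel_profile.unknown_count(),
        kb_version=kb.version,
    )
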