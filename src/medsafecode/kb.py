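"""Pharmacogenomic knowledge base: markers, star-allele definitions, CDS rules.

This module is the formal stand-in for an OWL 2 pharmacogenomics ontology.
Star alleles (haplotypes) are defined by a *sufficient* set of tag-SNP
variants — presence of every tag variant identifies the allele — plus a
*necessary* set listing all variants known to lie on the allele.  Clinical
decision-support (CDS) rules attach a recommendation message to a genotype
condition built from a small conjunctive language:

* ``HasSome(atom)``      — at least one chromosome carries the nucleotide;
* ``HasExactly(n, atom)``— exactly ``n`` of the two copies carry it (n ≤ 2);
* ``HasHaplotype(g, l)`` — the profile matches allele ``l`` of gene ``g``;
* ``And(children)``      — conjunction.

Instead of description-logic reasoning, knowledge-base quality control is
done by *finite-domain satisfiability*: a diploid genotype over the markers
referenced by a condition is a point in the finite product space of
unordered nucleotide pairs, and every check is decided by exhaustive
enumeration of that space.  For the conjunctive/cardinality fragment above
this has the same detection power as DL class-satisfiability checking.
"""

from __future__ import annotations

import itertools
import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence, Union

from .errors import CapacityError, KBLoadError, KBReferenceError

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")
CHROMOSOMES = frozenset(str(i) for i in range(1, 23)) | {"X", "Y", "MT"}

_RSID_RE = re.compile(r"^rs\d+$")
_ATOM_RE = re.compile(r"^(rs\d+)_([ACGT])$")

#: Diploid genotype: unordered nucleotide pair, stored sorted.
Pair = tuple[str, str]
#: Complete assignment of pairs to marker rsids.
Genotype = dict[str, Pair]


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class VariantAtom:
    """A single SNP variant symbol such as ``rs1057910_C``."""

    rsid: str
    nucleotide: str

    def __str__(self) -> str:
        return f"{self.rsid}_{self.nucleotide}"

    @classmethod
    def parse(cls, text: str) -> "VariantAtom":
        m = _ATOM_RE.match(text)
        if not m:
            raise KBLoadError(f"malformed variant atom {text!r} (expected rs<digits>_<A/C/G/T>)")
        return cls(m.group(1), m.group(2))


@dataclass(frozen=True)
class MarkerDefinition:
    """A panel SNP with its reference nucleotide and observable alleles."""

    rsid: str
    chromosome: str
    position: int
    reference: str
    allowed: tuple[str, ...]

    def pairs(self) -> list[Pair]:
        """All unordered diploid pairs, in lexicographic (min, max) order."""
        return list(itertools.combinations_with_replacement(sorted(self.allowed), 2))


@dataclass(frozen=True)
class HaplotypeDefinition:
    """A star allele: tag (sufficient) variants plus all known (necessary) variants."""

    gene: str
    label: str
    sufficient: frozenset[VariantAtom]
    necessary: frozenset[VariantAtom]
    metadata: Mapping[str, object] = field(default_factory=dict, compare=False, hash=False)

    @property
    def name(self) -> str:
        return f"{self.gene}{self.label}"


# --- condition AST ----------------------------------------------------------


@dataclass(frozen=True)
class HasSome:
    atom: VariantAtom


@dataclass(frozen=True)
class HasExactly:
    n: int
    atom: VariantAtom


@dataclass(frozen=True)
class HasHaplotype:
    gene: str
    label: str

    @property
    def name(self) -> str:
        return f"{self.gene}{self.label}"


@dataclass(frozen=True)
class And:
    children: tuple["ConditionExpr", ...]


ConditionExpr = Union[HasSome, HasExactly, HasHaplotype, And]


@dataclass(frozen=True)
class CDSRule:
    rule_id: str
    condition: ConditionExpr
    message: str
    source: str = ""


@dataclass(frozen=True)
class KnowledgeBase:
    """Markers (in panel order), star-allele definitions and CDS rules."""

    version: str
    build: str
    markers: tuple[MarkerDefinition, ...]
    haplotypes: tuple[HaplotypeDefinition, ...]
    rules: tuple[CDSRule, ...]
    panel_genes: tuple[str, ...] = ()

    @property
    def marker_map(self) -> dict[str, MarkerDefinition]:
        return {m.rsid: m for m in self.markers}

    @property
    def haplotype_map(self) -> dict[str, HaplotypeDefinition]:
        return {h.name: h for h in self.haplotypes}

    @property
    def panel(self) -> tuple[str, ...]:
        return tuple(m.rsid for m in self.markers)


# ---------------------------------------------------------------------------
# Condition (de)serialization


def condition_to_obj(cond: ConditionExpr) -> object:
    if isinstance(cond, HasSome):
        return {"has_some": str(cond.atom)}
    if isinstance(cond, HasExactly):
        return {"has_exactly": {"n": cond.n, "atom": str(cond.atom)}}
    if isinstance(cond, HasHaplotype):
        return {"has_haplotype": cond.name}
    if isinstance(cond, And):
        return {"and": [condition_to_obj(c) for c in cond.children]}
    raise TypeError(f"not a condition: {cond!r}")


def _split_haplotype_name(name: str) -> tuple[str, str]:
    star = name.find("*")
    if star <= 0:
        raise KBLoadError(f"malformed haplotype name {name!r} (expected GENE*label)")
    return name[:star], name[star:]


def condition_from_obj(obj: object, where: str) -> ConditionExpr:
    """Parse the nested-object condition serialization.

    Only the conjunctive fragment is accepted; any other construct (``or``,
    ``not``, ...) is a load error.
    """
    if not isinstance(obj, dict) or len(obj) != 1:
        raise KBLoadError(f"{where}: condition must be a single-key object, got {obj!r}")
    key, value = next(iter(obj.items()))
    if key == "has_some":
        return HasSome(VariantAtom.parse(str(value)))
    if key == "has_exactly":
        if not isinstance(value, dict) or set(value) != {"n", "atom"}:
            raise KBLoadError(f"{where}: has_exactly needs keys n and atom")
        n = value["n"]
        if not isinstance(n, int) or not 0 <= n <= 2:
            raise KBLoadError(f"{where}: has_exactly n must be an integer in 0..2, got {n!r}")
        return HasExactly(n, VariantAtom.parse(str(value["atom"])))
    if key == "has_haplotype":
        gene, label = _split_haplotype_name(str(value))
        return HasHaplotype(gene, label)
    if key == "and":
        if not isinstance(value, list) or not value:
            raise KBLoadError(f"{where}: 'and' needs a non-empty list of children")
        return And(tuple(condition_from_obj(c, where) for c in value))
    raise KBLoadError(f"{where}: unsupported condition construct {key!r}")


# ---------------------------------------------------------------------------
# Loading / saving


def _require(check: bool, message: str) -> None:
    if not check:
        raise KBLoadError(message)


def load_kb(path: Union[str, Path]) -> KnowledgeBase:
    """Load and validate a KB JSON file.

    Raises :class:`KBLoadError` naming the offending record on any schema
    violation, and :class:`KBReferenceError` for dangling cross-references.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, ValueError) as exc:
        raise KBLoadError(f"cannot read KB file {path}: {exc}") from exc
    return parse_kb(data, source=str(path))


def parse_kb(data: object, source: str = "<memory>") -> KnowledgeBase:
    _require(isinstance(data, dict), f"{source}: KB document must be a JSON object")
    assert isinstance(data, dict)
    for key in ("version", "build", "markers", "haplotypes", "rules"):
        _require(key in data, f"{source}: missing top-level key {key!r}")

    markers: list[MarkerDefinition] = []
    seen_rsids: set[str] = set()
    for rec in data["markers"]:
        rsid = str(rec.get("rsid", ""))
        where = f"marker {rsid or rec!r}"
        _require(_RSID_RE.match(rsid) is not None, f"{where}: bad rsid")
        _require(rsid not in seen_rsids, f"{where}: duplicate rsid")
        seen_rsids.add(rsid)
        chrom = str(rec.get("chromosome", ""))
        _require(chrom in CHROMOSOMES, f"{where}: bad chromosome {chrom!r}")
        pos = rec.get("position")
        _require(isinstance(pos, int) and pos >= 1, f"{where}: position must be a positive integer")
        allowed = tuple(str(x) for x in rec.get("allowed", ()))
        _require(len(allowed) >= 2, f"{where}: needs >= 2 allowed nucleotides")
        _require(all(a in NUCLEOTIDES for a in allowed), f"{where}: allowed nucleotides must be A/C/G/T")
        _require(len(set(allowed)) == len(allowed), f"{where}: duplicate allowed nucleotides")
        ref = str(rec.get("reference", ""))
        _require(ref == allowed[0], f"{where}: reference nucleotide must be first in allowed list")
        markers.append(MarkerDefinition(rsid, chrom, pos, ref, allowed))
    marker_map = {m.rsid: m for m in markers}

    def resolve_atom(atom: VariantAtom, where: str) -> None:
        if atom.rsid not in marker_map:
            raise KBReferenceError(f"{where}: references undefined marker {atom.rsid}")
        if atom.nucleotide not in marker_map[atom.rsid].allowed:
            raise KBLoadError(
                f"{where}: nucleotide {atom.nucleotide} not allowed for {atom.rsid} "
                f"(allowed: {'/'.join(marker_map[atom.rsid].allowed)})"
            )

    haplotypes: list[HaplotypeDefinition] = []
    seen_names: set[str] = set()
    for rec in data["haplotypes"]:
        gene = str(rec.get("gene", ""))
        label = str(rec.get("label", ""))
        where = f"haplotype {gene}{label}"
        _require(bool(gene) and label.startswith("*"), f"{where}: needs gene and '*'-prefixed label")
        name = gene + label
        _require(name not in seen_names, f"{where}: duplicate (gene, label)")
        seen_names.add(name)
        sufficient = frozenset(VariantAtom.parse(str(a)) for a in rec.get("sufficient", ()))
        necessary = frozenset(VariantAtom.parse(str(a)) for a in rec.get("necessary", ()))
        _require(bool(sufficient), f"{where}: sufficient atom set must be non-empty")
        for atom in sufficient | necessary:
            resolve_atom(atom, where)
        if not sufficient <= necessary:
            # Equivalent-class atoms are implicitly also necessary conditions.
            logger.warning("%s: sufficient atoms not contained in necessary set; uniting", where)
            necessary = necessary | sufficient
        haplotypes.append(
            HaplotypeDefinition(gene, label, sufficient, necessary, dict(rec.get("metadata", {})))
        )
    hap_names = {h.name for h in haplotypes}

    def resolve_condition(cond: ConditionExpr, where: str) -> None:
        if isinstance(cond, (HasSome, HasExactly)):
            resolve_atom(cond.atom, where)
        elif isinstance(cond, HasHaplotype):
            if cond.name not in hap_names:
                raise KBReferenceError(f"{where}: references undefined haplotype {cond.name}")
        elif isinstance(cond, And):
            for child in cond.children:
                resolve_condition(child, where)

    rules: list[CDSRule] = []
    seen_rule_ids: set[str] = set()
    for rec in data["rules"]:
        rule_id = str(rec.get("rule_id", ""))
        where = f"rule {rule_id or rec!r}"
        _require(bool(rule_id), f"{where}: missing rule_id")
        _require(rule_id not in seen_rule_ids, f"{where}: duplicate rule_id")
        seen_rule_ids.add(rule_id)
        message = str(rec.get("message", ""))
        _require(bool(message), f"{where}: message must be non-empty")
        cond = condition_from_obj(rec.get("condition"), where)
        resolve_condition(cond, where)
        rules.append(CDSRule(rule_id, cond, message, str(rec.get("source", ""))))

    return KnowledgeBase(
        version=str(data["version"]),
        build=str(data["build"]),
        markers=tuple(markers),
        haplotypes=tuple(haplotypes),
        rules=tuple(rules),
        panel_genes=tuple(str(g) for g in data.get("panel_genes", ())),
    )


def kb_to_dict(kb: KnowledgeBase) -> dict:
    return {
        "version": kb.version,
        "build": kb.build,
        "panel_genes": list(kb.panel_genes),
        "markers": [
            {
                "rsid": m.rsid,
                "chromosome": m.chromosome,
                "position": m.position,
                "reference": m.reference,
                "allowed": list(m.allowed),
            }
            for m in kb.markers
        ],
        "haplotypes": [
            {
                "gene": h.gene,
                "label": h.label,
                "sufficient": sorted(str(a) for a in h.sufficient),
                "necessary": sorted(str(a) for a in h.necessary),
                "metadata": dict(h.metadata),
            }
            for h in kb.haplotypes
        ],
        "rules": [
            {
                "rule_id": r.rule_id,
                "condition": condition_to_obj(r.condition),
                "message": r.message,
                "source": r.source,
            }
            for r in kb.rules
        ],
    }


def save_kb(kb: KnowledgeBase, path: Union[str, Path]) -> Path:
    """Write the KB as deterministic, human-diffable JSON."""
    path = Path(path)
    path.write_text(json.dumps(kb_to_dict(kb), indent=1) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Finite-domain satisfiability


def expand_condition(cond: ConditionExpr, kb: KnowledgeBase) -> ConditionExpr:
    """Replace every haplotype reference by its sufficient-atom conjunction."""
    if isinstance(cond, HasHaplotype):
        hap = kb.haplotype_map.get(cond.name)
        if hap is None:
            raise KBReferenceError(f"condition references undefined haplotype {cond.name}")
        return And(tuple(HasSome(a) for a in sorted(hap.sufficient, key=str)))
    if isinstance(cond, And):
        return And(tuple(expand_condition(c, kb) for c in cond.children))
    return cond


def referenced_markers(cond: ConditionExpr, kb: KnowledgeBase) -> set[str]:
    """Distinct marker rsids a condition depends on, through haplotype refs."""
    out: set[str] = set()

    def walk(c: ConditionExpr) -> None:
        if isinstance(c, (HasSome, HasExactly)):
            out.add(c.atom.rsid)
        elif isinstance(c, HasHaplotype):
            hap = kb.haplotype_map.get(c.name)
            if hap is None:
                raise KBReferenceError(f"condition references undefined haplotype {c.name}")
            out.update(a.rsid for a in hap.sufficient)
        elif isinstance(c, And):
            for child in c.children:
                walk(child)

    walk(cond)
    return out


def eval_complete(cond: ConditionExpr, genotype: Mapping[str, Pair], kb: KnowledgeBase) -> bool:
    """Two-valued evaluation over a complete genotype assignment."""
    if isinstance(cond, HasSome):
        return cond.atom.nucleotide in genotype[cond.atom.rsid]
    if isinstance(cond, HasExactly):
        return genotype[cond.atom.rsid].count(cond.atom.nucleotide) == cond.n
    if isinstance(cond, HasHaplotype):
        hap = kb.haplotype_map[cond.name]
        return all(a.nucleotide in genotype[a.rsid] for a in hap.sufficient)
    if isinstance(cond, And):
        return all(eval_complete(c, genotype, kb) for c in cond.children)
    raise TypeError(f"not a condition: {cond!r}")


def genotype_space(rsids: Sequence[str], kb: KnowledgeBase) -> Iterator[Genotype]:
    """All complete diploid genotypes over the given markers (lazy product)."""
    marker_map = kb.marker_map
    pair_lists = [marker_map[r].pairs() for r in rsids]
    for combo in itertools.product(*pair_lists):
        yield dict(zip(rsids, combo))


DEFAULT_MAX_MARKERS = 12


def satisfiable(
    cond: ConditionExpr,
    kb: KnowledgeBase,
    max_markers: int = DEFAULT_MAX_MARKERS,
    entity: str = "condition",
) -> tuple[bool, Optional[Genotype]]:
    """Decide by exhaustive enumeration whether any complete diploid genotype
    over the condition's referenced markers satisfies it.

    Returns ``(True, witness)`` with a concrete satisfying genotype, or
    ``(False, None)``.  Raises :class:`CapacityError` when the condition
    references more than ``max_markers`` distinct markers.
    """
    rsids = sorted(referenced_markers(cond, kb))
    if len(rsids) > max_markers:
        raise CapacityError(
            f"{entity}: references {len(rsids)} markers, exceeding the "
            f"enumeration bound of {max_markers}"
        )
    for genotype in genotype_space(rsids, kb):
        if eval_complete(cond, genotype, kb):
            return True, genotype
    return False, None


# ---------------------------------------------------------------------------
# Consistency checking


class FindingCategory(str, Enum):
    DUPLICATE_DEFINITION = "DUPLICATE_DEFINITION"
    TAG_NOT_ENTAILING = "TAG_NOT_ENTAILING"
    UNSATISFIABLE_HAPLOTYPE = "UNSATISFIABLE_HAPLOTYPE"
    UNSATISFIABLE_RULE = "UNSATISFIABLE_RULE"


@dataclass(frozen=True)
class Finding:
    category: FindingCategory
    entity_id: str
    detail: str = ""

    def __str__(self) -> str:
        return f"{self.category.value}\t{self.entity_id}\t{self.detail}"


def check_consistency(
    kb: KnowledgeBase, max_markers_per_check: int = DEFAULT_MAX_MARKERS
) -> list[Finding]:
    """Audit the KB for definitional errors by exhaustive genotype enumeration.

    Categories:

    * ``UNSATISFIABLE_HAPLOTYPE`` — no complete diploid genotype satisfies the
      allele's sufficient (tag) conjunction;
    * ``TAG_NOT_ENTAILING`` — a necessary atom can never hold together with
      the tag conjunction (the definition contradicts itself);
    * ``DUPLICATE_DEFINITION`` — two alleles of one gene share a tag set;
    * ``UNSATISFIABLE_RULE`` — no complete genotype triggers the rule.

    Findings are returned sorted by (category, entity id) so repeated runs
    on the same KB are byte-identical.  A condition referencing more markers
    than ``max_markers_per_check`` raises :class:`CapacityError` naming the
    entity; it is never silently skipped.
    """
    findings: list[Finding] = []

    by_gene_tags: dict[tuple[str, frozenset[VariantAtom]], list[str]] = {}
    for hap in kb.haplotypes:
        by_gene_tags.setdefault((hap.gene, hap.sufficient), []).append(hap.name)
    for (_gene, _tags), names in by_gene_tags.items():
        if len(names) > 1:
            findings.append(
                Finding(
                    FindingCategory.DUPLICATE_DEFINITION,
                    "==".join(sorted(names)),
                    "identical sufficient (tag) atom sets",
                )
            )

    for hap in kb.haplotypes:
        suff_cond = And(tuple(HasSome(a) for a in sorted(hap.sufficient, key=str)))
        sat, _ = satisfiable(suff_cond, kb, max_markers_per_check, entity=f"haplotype {hap.name}")
        if not sat:
            findings.append(
                Finding(
                    FindingCategory.UNSATISFIABLE_HAPLOTYPE,
                    hap.name,
                    "no diploid genotype satisfies the sufficient atom conjunction",
                )
            )
            continue
        for atom in sorted(hap.necessary - hap.sufficient, key=str):
            both = And(suff_cond.children + (HasSome(atom),))
            sat, _ = satisfiable(both, kb, max_markers_per_check, entity=f"haplotype {hap.name}")
            if not sat:
                findings.append(
                    Finding(
                        FindingCategory.TAG_NOT_ENTAILING,
                        hap.name,
                        f"necessary atom {atom} can never hold when the tag set matches",
                    )
                )

    for rule in kb.rules:
        sat, _ = satisfiable(rule.condition, kb, max_markers_per_check, entity=f"rule {rule.rule_id}")
        if not sat:
            findings.append(
                Finding(
                    FindingCategory.UNSATISFIABLE_RULE,
                    rule.rule_id,
                    "no diploid genotype satisfies the rule condition",
                )
            )

    findings.sort(key=lambda f: (f.category.value, f.entity_id, f.detail))
    return findings
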