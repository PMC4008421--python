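"""Self-contained test-data generators: no downloads, pure functions of seed.

``build_paper_fixture_kb`` holds the worked example this toolkit is built
around: the CYP2C9*3 star allele (tag variant rs1057910_C, with
rs1057911_A / rs1799853_C / rs2256871_A as additional known variants), an
invented CYP2C9*1 reference-allele definition, and the warfarin
starting-dose rule that fires on a *1/*3-compatible genotype homozygous for
rs9923231_T (VKORC1 -1639G>A, reported in C/T orientation).  The 58-gene
clinical pharmacogenomics panel is carried as panel metadata.

Chromosome coordinates for rs1057911, rs1799853 and rs2256871 are
approximate placeholders on GRCh37 (positions only serve the VCF
chromosome+position fallback match); rs1057910 and rs9923231 use real
GRCh37 coordinates.

``generate_synthetic_kb`` pads the panel with deterministic synthetic
biallelic markers in an obviously fake rsid namespace (``rs99…``) up to a
target size — by default 385 markers, the size of a full clinical panel —
each with a synthetic *1/*2 allele pair.  ``sample_profile`` draws random
diploid genotypes with a configurable alternate-allele frequency and
missing rate, and the ``write_*`` functions emit files in both supported
dialects that re-parse to the original profile.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Union

from .genotype_io import UNKNOWN, Call, GenotypeProfile, normalize_pair
from .kb import (
    And,
    CDSRule,
    HasExactly,
    HasHaplotype,
    HaplotypeDefinition,
    KnowledgeBase,
    MarkerDefinition,
    VariantAtom,
)

#: The 58 genes of the clinical pharmacogenomics panel, in panel order.
PANEL_GENES = (
    "ABCB1", "ABCC2", "ABCG2", "ACE", "ADRB1", "ADRB2", "AHR", "ALOX5",
    "BRCA1", "COMT", "CYP1A1", "CYP1A2", "CYP2A6", "CYP2B6", "CYP2C19",
    "CYP2C8", "CYP2C9", "CYP2D6", "CYP2J2", "CYP3A4", "CYP3A5", "DPYD",
    "DRD2", "F5", "G6PD", "GSTM1", "GSTP1", "HLA-B*1502", "HLA-B*5701",
    "HMGCR", "IL28B", "KCNH2", "KCNJ11", "MTHFR", "NAT1", "NAT2", "NQO1",
    "NR1I2", "P2RY1", "P2RY12", "PTGIS", "PTGS2", "SCN5A", "SLC15A2",
    "SLC19A1", "SLC22A1", "SLC22A2", "SLC22A6", "SLCO1B1", "SLCO1B3",
    "SLCO2B1", "SULT1A1", "TPMT", "TYMS", "UGT1A1", "UGT2B15", "UGT2B7",
    "VKORC1",
)

WARFARIN_RULE9_MESSAGE = (
    "0.5–2 mg warfarin per day should be considered as a starting dose "
    "range for a patient with this genotype according to the warfarin drug label."
)

DEFAULT_PANEL_SIZE = 385


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study panel and sampled profiles."""

    n_markers: int = DEFAULT_PANEL_SIZE
    seed: int = 0
    missing_rate: float = 0.02  # consumer-array no-call rates are a few percent
    alt_freq: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate must be in [0, 1], got {self.missing_rate}")
        if not 0.0 <= self.alt_freq <= 1.0:
            raise ValueError(f"alt_freq must be in [0, 1], got {self.alt_freq}")


def build_paper_fixture_kb() -> KnowledgeBase:
    """The worked-example KB: CYP2C9 *1/*3 and the warfarin starting-dose rule."""
    markers = (
        MarkerDefinition("rs1057910", "10", 96741053, "A", ("A", "C")),
        MarkerDefinition("rs1057911", "10", 96741058, "A", ("A", "T")),
        MarkerDefinition("rs1799853", "10", 96702047, "C", ("C", "T")),
        MarkerDefinition("rs2256871", "10", 96709038, "A", ("A", "G")),
        MarkerDefinition("rs9923231", "16", 31107689, "C", ("C", "T")),
    )
    star3_necessary = frozenset(
        {
            VariantAtom("rs1057910", "C"),
            VariantAtom("rs1057911", "A"),
            VariantAtom("rs1799853", "C"),
            VariantAtom("rs2256871", "A"),
        }
    )
    haplotypes = (
        HaplotypeDefinition(
            gene="CYP2C9",
            label="*1",
            sufficient=frozenset(
                {VariantAtom("rs1057910", "A"), VariantAtom("rs1799853", "C")}
            ),
            necessary=frozenset(
                {VariantAtom("rs1057910", "A"), VariantAtom("rs1799853", "C")}
            ),
            # No published tag-set exists for the reference allele; this
            # definition (reference nucleotides at the *2/*3-defining
            # positions) is a documented convention of this toolkit.
            metadata={"invented": True},
        ),
        HaplotypeDefinition(
            gene="CYP2C9",
            label="*3",
            sufficient=frozenset({VariantAtom("rs1057910", "C")}),
            necessary=star3_necessary,
        ),
    )
    rules = (
        CDSRule(
            rule_id="rule9",
            condition=And(
                (
                    HasHaplotype("CYP2C9", "*1"),
                    HasHaplotype("CYP2C9", "*3"),
                    HasExactly(2, VariantAtom("rs9923231", "T")),
                )
            ),
            message=WARFARIN_RULE9_MESSAGE,
            source="FDA label (Coumadin, Bristol-Myers Squibb)",
        ),
    )
    return KnowledgeBase(
        version="v0.2",
        build="GRCh37",
        markers=markers,
        haplotypes=haplotypes,
        rules=rules,
        panel_genes=PANEL_GENES,
    )


def generate_synthetic_kb(spec: FixtureSpec) -> KnowledgeBase:
    """Extend the fixture KB with synthetic biallelic markers up to n_markers.

    Synthetic markers use the fake ``rs99…`` namespace, one synthetic gene
    per marker with a *1 (reference) / *2 (alternate) allele pair.  The
    output is a pure function of ``spec.seed``.
    """
    base = build_paper_fixture_kb()
    if spec.n_markers < len(base.markers):
        raise ValueError(
            f"n_markers={spec.n_markers} is below the {len(base.markers)} fixture markers"
        )
    rng = random.Random(spec.seed)
    markers = list(base.markers)
    haplotypes = list(base.haplotypes)
    for i in range(spec.n_markers - len(base.markers)):
        rsid = f"rs99{i + 1:05d}"
        ref, alt = rng.sample("ACGT", 2)
        chrom = str(1 + i % 22)
        marker = MarkerDefinition(rsid, chrom, 1_000_000 + 1_000 * i, ref, (ref, alt))
        markers.append(marker)
        gene = f"SYN{i + 1:04d}"
        haplotypes.append(
            HaplotypeDefinition(
                gene, "*1",
                frozenset({VariantAtom(rsid, ref)}),
                frozenset({VariantAtom(rsid, ref)}),
                metadata={"synthetic": True},
            )
        )
        haplotypes.append(
            HaplotypeDefinition(
                gene, "*2",
                frozenset({VariantAtom(rsid, alt)}),
                frozenset({VariantAtom(rsid, alt)}),
                metadata={"synthetic": True},
            )
        )
    return KnowledgeBase(
        version=base.version,
        build=base.build,
        markers=tuple(markers),
        haplotypes=tuple(haplotypes),
        rules=base.rules,
        panel_genes=base.panel_genes,
    )


def sample_profile(kb: KnowledgeBase, spec: FixtureSpec) -> GenotypeProfile:
    """Draw a random diploid profile over the KB panel (deterministic per seed).

    Each of the two nucleotides at a marker is an alternate allele with
    probability ``alt_freq`` (uniform over the non-reference alleles),
    otherwise the reference; the whole call is then masked to UNKNOWN with
    probability ``missing_rate``.
    """
    rng = random.Random(spec.seed)
    calls: dict[str, Call] = {}
    for marker in kb.markers:
        alts = [a for a in marker.allowed if a != marker.reference]
        pair = tuple(
            rng.choice(alts) if rng.random() < spec.alt_freq else marker.reference
            for _ in range(2)
        )
        if rng.random() < spec.missing_rate:
            calls[marker.rsid] = UNKNOWN
        else:
            calls[marker.rsid] = normalize_pair(pair[0], pair[1])
    return GenotypeProfile(calls=calls, source_format="manual", build=kb.build)


# ---------------------------------------------------------------------------
# Writers (inverse of the genotype_io parsers)


def write_23andme(profile: GenotypeProfile, kb: KnowledgeBase, out: IO[str]) -> None:
    """Emit the profile in the 23andMe 4-column dialect (UNKNOWN as ``--``)."""
    out.write("# This data file is a synthetic genotype profile.\n")
    out.write("# rsid\tchromosome\tposition\tgenotype\n")
    for marker in kb.markers:
        call = profile.calls.get(marker.rsid, UNKNOWN)
        token = "--" if call is UNKNOWN else "".join(call)
        out.write(f"{marker.rsid}\t{marker.chromosome}\t{marker.position}\t{token}\n")


def write_vcf(profile: GenotypeProfile, kb: KnowledgeBase, out: IO[str]) -> None:
    """Emit a variant-only single-sample VCF.

    Homozygous-reference markers are omitted (missing-means-reference
    convention); UNKNOWN markers are written with GT ``./.`` so the file
    re-parses to the original profile.
    """
    out.write("##fileformat=VCFv4.2\n")
    out.write("##source=medsafecode\n")
    seen: list[str] = []
    for marker in kb.markers:
        if marker.chromosome not in seen:
            seen.append(marker.chromosome)
            out.write(f"##contig=<ID={marker.chromosome}>\n")
    out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
    for marker in kb.markers:
        call = profile.calls.get(marker.rsid, UNKNOWN)
        if call == (marker.reference, marker.reference):
            continue
        if call is UNKNOWN:
            alt_field, gt = ".", "./."
        else:
            alts = sorted({b for b in call if b != marker.reference})
            alleles = [marker.reference] + alts
            idx = sorted(alleles.index(b) for b in call)
            alt_field, gt = ",".join(alts), f"{idx[0]}/{idx[1]}"
        out.write(
            f"{marker.chromosome}\t{marker.position}\t{marker.rsid}\t"
            f"{marker.reference}\t{alt_field}\t.\t.\t.\tGT\t{gt}\n"
        )


def write_profile_files(
    profile: GenotypeProfile, kb: KnowledgeBase, directory: Union[str, Path]
) -> tuple[Path, Path]:
    """Write both dialects into a directory; returns (tsv_path, vcf_path)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tsv_path = directory / "profile.txt"
    vcf_path = directory / "profile.vcf"
    with tsv_path.open("w", encoding="utf-8") as fh:
        write_23andme(profile, kb, fh)
    with vcf_path.open("w", encoding="utf-8") as fh:
        write_vcf(profile, kb, fh)
    return tsv_path, vcf_path
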