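"""Parse patient genotype files into a normalized diploid profile.

Two input dialects are supported: the 23andMe consumer download format
(tab-separated rsid/chromosome/position/genotype) and single-sample VCF.
Calls are stored as unordered, sorted nucleotide pairs; a marker whose
genotype could not be determined carries the ``UNKNOWN`` sentinel (``None``).

Two conventions from the underlying code system apply here:

* **missing means reference** — a panel marker with no record in a
  variant-only VCF is homozygous for the KB's reference nucleotide;
* **strand orientation** — 23andMe files may be reported on either strand;
  parsing with ``orientation="reverse"`` complements every nucleotide before
  storage.  KB nucleotides are defined on the forward strand of the
  reference build, and forward is the default assumption about input files.
"""

from __future__ import annotations

import io
import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Optional, Union

import pysam

from .errors import FormatError, GenotypeParseError
from .kb import KnowledgeBase

logger = logging.getLogger(__name__)

#: Sentinel for a marker whose diploid genotype is not known.
UNKNOWN = None

Pair = tuple[str, str]
Call = Optional[Pair]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = frozenset("ACGT")
_AUTOSOMES = frozenset(str(i) for i in range(1, 23))


@dataclass
class GenotypeProfile:
    """Per-marker unordered diploid nucleotide pairs with explicit unknowns."""

    calls: dict[str, Call] = field(default_factory=dict)
    source_format: str = "manual"  # one of 23andme / vcf / code / manual
    build: str = ""

    def known_count(self) -> int:
        return sum(1 for c in self.calls.values() if c is not UNKNOWN)

    def unknown_count(self) -> int:
        return sum(1 for c in self.calls.values() if c is UNKNOWN)


def normalize_pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def complement(nucleotide: str) -> str:
    return _COMPLEMENT[nucleotide]


# ---------------------------------------------------------------------------
# Format detection


def detect_format(stream: IO[str]) -> str:
    """Sniff a genotype text stream: ``"vcf"``, ``"23andme"`` or ``"unknown"``.

    Raises :class:`FormatError` on an empty stream.  The stream is consumed.
    """
    first_data_line = None
    saw_anything = False
    for line in stream:
        if line.strip():
            saw_anything = True
            if line.startswith("##fileformat=VCF"):
                return "vcf"
            if line.startswith("#"):
                continue
            first_data_line = line
            break
    if not saw_anything:
        raise FormatError("empty genotype stream")
    if first_data_line is not None:
        cols = first_data_line.rstrip("\n").split("\t")
        if len(cols) == 4 and cols[0].startswith("rs"):
            return "23andme"
    return "unknown"


# ---------------------------------------------------------------------------
# 23andMe


def parse_23andme(stream: IO[str], orientation: str = "forward") -> GenotypeProfile:
    """Parse a 23andMe-dialect TSV into a profile.

    Genotype tokens of two bases give a call; ``--`` or tokens containing
    ``I``/``D`` (indels) give UNKNOWN; a single base is kept as a homozygous
    pair on X/Y/MT and recorded as UNKNOWN (with a warning) on autosomes.
    With ``orientation="reverse"`` every base is complemented before storage.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be 'forward' or 'reverse', got {orientation!r}")
    flip = orientation == "reverse"
    calls: dict[str, Call] = {}
    skipped_ids = 0
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 4:
            raise GenotypeParseError(
                f"line {lineno}: expected 4 tab-separated columns, got {len(cols)}"
            )
        rsid, chrom, _pos, genotype = cols
        if not rsid.startswith("rs"):
            skipped_ids += 1  # internal ids such as i3000001
            continue
        genotype = genotype.strip().upper()
        if "-" in genotype or "I" in genotype or "D" in genotype or not genotype:
            calls[rsid] = UNKNOWN
            continue
        if not set(genotype) <= _BASES or len(genotype) > 2:
            raise GenotypeParseError(f"line {lineno}: bad genotype token {genotype!r}")
        bases = [(_COMPLEMENT[b] if flip else b) for b in genotype]
        if len(bases) == 1:
            if chrom in _AUTOSOMES:
                logger.warning(
                    "line %d: single-base genotype on autosomal marker %s; recording UNKNOWN",
                    lineno,
                    rsid,
                )
                calls[rsid] = UNKNOWN
            else:
                calls[rsid] = (bases[0], bases[0])  # hemizygous X/Y/MT as homozygous pair
            continue
        calls[rsid] = normalize_pair(bases[0], bases[1])
    if skipped_ids:
        logger.info("skipped %d non-rs identifiers", skipped_ids)
    return GenotypeProfile(calls=calls, source_format="23andme")


# ---------------------------------------------------------------------------
# VCF


def _norm_chrom(chrom: str) -> str:
    chrom = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return "MT" if chrom in ("M", "MT") else chrom


def parse_vcf(source: Union[str, Path, IO[str]], kb: KnowledgeBase) -> GenotypeProfile:
    """Parse a single-sample VCF against the KB panel.

    Every panel marker starts as homozygous reference; records then override
    by rsid (ID column) or, failing that, by (chromosome, position).  A GT of
    ``./.`` or a half-call sets UNKNOWN, as does a called allele that is not
    a single A/C/G/T base in the marker's allowed set.
    """
    if hasattr(source, "read"):
        with tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False) as tmp:
            tmp.write(source.read())  # type: ignore[union-attr]
            tmp_path = tmp.name
        try:
            return _parse_vcf_path(tmp_path, kb)
        finally:
            Path(tmp_path).unlink(missing_ok=True)
    return _parse_vcf_path(str(source), kb)


def _parse_vcf_path(path: str, kb: KnowledgeBase) -> GenotypeProfile:
    marker_map = kb.marker_map
    by_pos = {(m.chromosome, m.position): m for m in kb.markers}
    calls: dict[str, Call] = {m.rsid: (m.reference, m.reference) for m in kb.markers}

    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise GenotypeParseError(f"cannot parse VCF: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise GenotypeParseError(
                f"expected a single-sample VCF, found {len(samples)} samples; "
                "extract one sample first (e.g. with a --sample selection or "
                "'bcftools view -s NAME')"
            )
        off_panel = 0
        for rec in vf:
            marker = None
            if rec.id and rec.id in marker_map:
                marker = marker_map[rec.id]
            else:
                marker = by_pos.get((_norm_chrom(rec.chrom), rec.pos))
            if marker is None:
                off_panel += 1
                continue
            sample = rec.samples[0]
            if "GT" not in sample:
                raise GenotypeParseError(
                    f"record {rec.chrom}:{rec.pos}: GT subfield required but absent"
                )
            gt = sample["GT"]
            alleles = (rec.ref,) + tuple(rec.alts or ())
            if gt is None or all(i is None for i in gt):
                calls[marker.rsid] = UNKNOWN
                continue
            if any(i is None for i in gt):
                logger.warning("record %s:%d: half-call GT; recording UNKNOWN", rec.chrom, rec.pos)
                calls[marker.rsid] = UNKNOWN
                continue
            try:
                bases = [str(alleles[i]).upper() for i in gt]
            except IndexError:
                raise GenotypeParseError(
                    f"record {rec.chrom}:{rec.pos}: GT index outside REF/ALT list"
                ) from None
            if len(bases) == 1:
                bases = bases * 2  # haploid call (X/Y/MT) stored as homozygous pair
            if any(len(b) != 1 or b not in _BASES for b in bases):
                logger.warning(
                    "record %s:%d: non-SNP allele in GT for %s; recording UNKNOWN",
                    rec.chrom,
                    rec.pos,
                    marker.rsid,
                )
                calls[marker.rsid] = UNKNOWN
                continue
            if any(b not in marker.allowed for b in bases):
                logger.warning(
                    "record %s:%d: allele not in allowed set for %s; recording UNKNOWN",
                    rec.chrom,
                    rec.pos,
                    marker.rsid,
                )
                calls[marker.rsid] = UNKNOWN
                continue
            calls[marker.rsid] = normalize_pair(bases[0], bases[1])
        if off_panel:
            logger.info("ignored %d VCF records outside the KB panel", off_panel)
    return GenotypeProfile(calls=calls, source_format="vcf", build=kb.build)


# ---------------------------------------------------------------------------
# Panel restriction


def restrict_to_panel(profile: GenotypeProfile, kb: KnowledgeBase) -> GenotypeProfile:
    """Project a profile onto exactly the KB panel (idempotent).

    Panel markers absent from the input become UNKNOWN; off-panel calls are
    dropped (their count is logged).
    """
    calls: dict[str, Call] = {}
    for marker in kb.markers:
        calls[marker.rsid] = profile.calls.get(marker.rsid, UNKNOWN)
    dropped = len(set(profile.calls) - set(calls))
    if dropped:
        logger.info("dropped %d off-panel calls", dropped)
    return GenotypeProfile(calls=calls, source_format=profile.source_format, build=profile.build or kb.build)
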