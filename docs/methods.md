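# Methods

`medsafecode` implements a desk-scale pharmacogenomic decision-support
pipeline: a patient's genotypes at a fixed panel of pharmacogenomic SNPs are
bit-packed into a compact, versioned URL (renderable as a QR code), and any
holder of that code can decode it and evaluate a knowledge base of
star-allele definitions and clinical decision-support (CDS) rules against
it. This note records the model, the conventions the implementation fixes,
and the choices made where the design was genuinely open.

## The knowledge-base model

The knowledge base (KB) is a JSON document (`docs/kb.schema.json`) with
three layers:

* **Markers.** Each panel SNP has a dbSNP rsid, a chromosome/position on a
  named reference build, a reference nucleotide, and an ordered list of 2–4
  observable nucleotides (reference first). Nucleotides are defined on the
  forward strand of the reference build, with one documented exception:
  VKORC1 −1639G>A (rs9923231) is stated in its conventional C/T reporting
  orientation so that the rule atom `rs9923231_T` has its familiar reading.

* **Star alleles.** A haplotype (e.g. `CYP2C9*3`) is defined by a
  *sufficient* set of tag-SNP variant atoms — presence of every tag variant
  on at least one chromosome identifies the allele — and a *necessary* set
  listing all variants known to lie on the allele. This mirrors the
  equivalent-class / subclass pattern used when such definitions are
  written in a description logic. A sufficient set not contained in its
  necessary set is repaired at load time by uniting the two (with a logged
  warning), since an identifying condition is trivially also a necessary
  one.

* **CDS rules.** A rule attaches a free-text recommendation (with its
  guideline source) to a genotype condition in a deliberately small
  conjunctive language: `has_some atom`, `has_exactly n atom` (n ∈ {0,1,2}
  over the two chromosome copies), `has_haplotype GENE*label`, and `and`.
  Disjunction and negation are not part of the language and are rejected at
  load time; every published axiom pattern this package targets is
  conjunctive, and the restriction is what makes exhaustive checking cheap.

### Reference alleles

Public allele nomenclatures do not define a tag set for `*1`-type
reference alleles; they are "none of the variants". The bundled KB defines
`CYP2C9*1` explicitly as the reference nucleotides at the `*2`/`*3`-defining
positions (`rs1057910_A`, `rs1799853_C`) and flags the definition as an
invented convention in its metadata. Under unphased data this makes a
compound heterozygote match both `*1` and `*3`, which is exactly the
presence semantics the rule conditions assume.

## Three-valued inference

Profiles are diploid, unordered and possibly incomplete: each panel marker
carries either a nucleotide pair or an explicit UNKNOWN. Evaluation returns
TRUE / FALSE / UNKNOWN per condition:

* an atom over an UNKNOWN marker is UNKNOWN; otherwise its nucleotide count
  in the pair decides;
* conjunction is strong Kleene: FALSE dominates, all-TRUE is TRUE,
  otherwise UNKNOWN.

Kleene conjunction alone is sound but can report UNKNOWN for a condition
that is false under *every* way of filling in the missing genotypes
(e.g. `has_exactly 0 rs1_A and has_some rs1_A`). Statuses are therefore
refined against the completion semantics: when the Kleene result is
UNKNOWN, the evaluator enumerates all completions of the unknown referenced
markers (haplotype references expanded to their tag conjunctions) and
reports FALSE if none satisfies the condition. The reported status is then
exactly TRUE / FALSE / UNKNOWN according to whether the condition holds
under all / none / some-but-not-all completions — the package's headline
correctness property, tested against an independent enumeration oracle on
200 random KBs. A TRUE-refinement is unnecessary: in this conjunctive
fragment a condition cannot hold under every completion while a referenced
marker is unknown. For the same reason, rule conditions are evaluated with
haplotype references expanded rather than by substituting per-allele
statuses, which would lose joint constraints between alleles sharing a
marker. Completion enumeration is capped at 12 unknown markers per
condition; beyond the cap the status stays UNKNOWN (clinical rules
reference far fewer).

UNKNOWN rule outcomes are reported with the list of missing markers. This
"insufficient data" channel is an addition of this implementation; it
preserves the safety-relevant distinction between "rule does not apply" and
"cannot tell", which a binary closed-world evaluation would erase. Whether
the original ontology-based service surfaced partial matches was never
specified.

No diplotype phasing or allele-pair assignment is attempted: the calls are
per-allele *presence* classes, faithful to the existential (`has some`)
style of the source axioms. Consequence: trans/cis ambiguity can over-call
compound diplotypes on unphased data.

## Knowledge-base consistency checking

Description-logic reasoning over the KB is replaced by closed-world
finite-domain satisfiability: the genotype space of a condition is the
product, over its referenced markers, of all unordered nucleotide pairs
(3 pairs for a biallelic marker, 6 for three alleles, 10 for four), and
every check enumerates it exhaustively. The checker reports, sorted by
(category, entity) for byte-identical reruns:

* `UNSATISFIABLE_HAPLOTYPE` — no diploid genotype satisfies the tag
  conjunction (e.g. three distinct required nucleotides at one marker);
* `TAG_NOT_ENTAILING` — some necessary atom can *never* hold together with
  the tag conjunction. This is the class-unsatisfiability reading: a
  necessary atom on an independent marker is merely not forced by the tag,
  which is the normal shape of such definitions and is not flagged;
* `DUPLICATE_DEFINITION` — two alleles of one gene with identical tag sets;
* `UNSATISFIABLE_RULE` — no genotype triggers the rule (e.g. `has_exactly 2`
  of two different nucleotides at one marker).

`max_markers_per_check` defaults to 12 (≈5·10⁵ genotypes for biallelic
markers — seconds of work); a condition exceeding it raises a capacity
error naming the entity rather than being skipped silently. The checker is
validated against an independent brute-force loop on 200 random KBs with
seeded defect injections (100 % detection required).

## The code dialect

The bit layout is a pure function of the KB. Slots follow panel order; a
marker with G unordered pairs gets ⌈log₂(G+1)⌉ bits (2 bits for a
biallelic SNP); value 0 always means UNKNOWN and values 1..G enumerate the
pairs in lexicographic (min, max) order. Slot values are written
MSB-first, the bit string is zero-padded to a multiple of 6, and 6-bit
groups map through the base64url alphabet (`A–Z a–z 0–9 - _`, chosen
because published example payloads contain `-` and `_`). The payload is
embedded as `<base_url><version>/<payload>` with `v0.2` as the default
version label; version mismatch at decode is an error, never a silent
fallback. A full 385-marker biallelic panel packs to 770 bits = 129
characters, well inside QR capacity.

The original service's bit assignment was never published: this layout is a
defined, documented dialect. Published example URLs parse (`parse_url`)
but do not decode against this KB. Raw genotypes, not derived
alleles/phenotypes, are encoded; an allele-level dialect would be a second
code version.

## QR rendering

No QR library is part of the supported dependency set, so the package
includes a minimal byte-mode QR encoder (`_qr.py`): the ISO/IEC 18004
error-correction block table for all 40 versions × 4 levels, Reed–Solomon
over GF(2⁸) (polynomial 0x11D), zig-zag placement, mask selection by the
four penalty rules, and BCH-coded format/version fields. The transcribed
block table is cross-checked in the test suite against the per-version
total codeword count derived independently from symbol geometry (module
counting), and the BCH fields against published reference vectors.
Rendering picks the smallest version whose data capacity holds the URL at
the requested error-correction level (default M — a robustness/print-size
balance) and writes a PNG via Pillow with the standard 4-module quiet
zone. Symbol *decoding* (the camera side) is out of scope.

## File-format conventions

* **23andMe dialect**: tab-separated rsid/chromosome/position/genotype,
  `#` comments; `--` or `I`/`D` tokens are UNKNOWN; non-`rs` internal ids
  are skipped; a single-base genotype is kept as a homozygous pair on
  X/Y/MT and recorded UNKNOWN (with a warning) on autosomes, so that
  cardinality atoms always see a uniform count of 2. The orientation flag
  is the caller's assertion about the file, default forward.
* **VCF**: single-sample v4.x with GT required; both `/` and `|` accepted
  (phase ignored). Matching prefers the ID column and falls back to
  chromosome+position. Every panel marker missing from a variant-only VCF
  is homozygous reference (missing-means-reference); `./.` and half-calls
  are UNKNOWN; a GT selecting a non-SNP or disallowed allele sets the
  marker UNKNOWN with a warning (indel refinement is out of scope). No
  liftover between builds and no imputation are attempted.

## Synthetic data

The bundled fixture KB transcribes the worked examples this package is
built around (the `CYP2C9*3` definition with its four necessary atoms, the
warfarin starting-dose rule, the 58-gene panel list). The full 385-SNP
panel list was never published, so `generate_synthetic_kb` pads the fixture
with deterministic biallelic markers in an obviously fake rsid namespace
(`rs99…`) — default 385 markers, matching a full clinical panel — each
with a synthetic `*1`/`*2` allele pair. `sample_profile` draws genotypes
i.i.d. with per-allele alternate frequency 0.2 and a 2 % no-call rate
(typical of consumer arrays). The generator makes no attempt at linkage
structure, realistic allele-frequency spectra, or population
stratification, and its fixture coordinates for three of the five CYP2C9
markers are approximate placeholders; passing tests therefore demonstrate
the correctness of the encoding, inference and checking machinery, not
concordance with any real cohort or the defunct original ontology. All
generators are pure functions of their seed; repeated runs are
byte-identical.

## Problem sizes

The test suite runs the codec identity on 500 random full-panel profiles,
and both oracle suites on 200 random KBs with at most 6 markers per KB —
small enough that exhaustive completion/genotype enumeration (≤ 6⁶ points)
is an uncontested ground truth, and the whole suite completes in seconds.
`scripts/acceptance.py` reruns the full encode→decode→interpret chain on
the fixture KB and a 385-marker synthetic panel.

## Known limitations

* No phenotype (metabolizer-status) layer, no drug–drug(-gene)
  interactions, no dosing arithmetic: rules map genotype conditions to
  vetted guideline text only.
* Per-marker dbSNP strand quirks in 23andMe exports are not corrected
  individually; the orientation flag applies to the whole file.
* The consistency checker's guarantees are relative to the conjunctive
  condition language; a richer language would need a real SAT encoding.
* The KB JSON schema ships as documentation; runtime validation is the
  loader's own (it produces record-level error messages the generic schema
  check could not).
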