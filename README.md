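# medsafecode

Pharmacogenomic decision support from a compact, anonymous genotype code.

Genotype-guided prescribing needs a patient's pharmacogenomic marker
genotypes to be available at the point of care without a central genetic
database. `medsafecode` implements that idea end to end at desk scale: it
parses a genotype file (23andMe export or single-sample VCF), packs the
panel genotypes into a short versioned URL — the *Medicine Safety Code* —
renderable as a QR code, decodes such codes back, and interprets them
against a formal knowledge base of star-allele definitions and clinical
decision-support (CDS) rules. No identity fields exist anywhere in the data
model; the code carries genotypes only.

It is aimed at people building or studying pharmacogenomic CDS pipelines:
the knowledge base, the code dialect, and the inference semantics are all
explicit, machine-checkable and unit-tested.

## The model in brief

* A **star allele** (e.g. CYP2C9\*3) is defined by a *sufficient* tag-SNP
  set — presence of every tag variant identifies the allele — plus a
  *necessary* set of all variants known to lie on it:

  ```
  CYP2C9*3  ≡  has some rs1057910_C
  CYP2C9*3  ⊑  has some rs1057911_A ⊓ has some rs1799853_C ⊓ has some rs2256871_A
  ```

* A **CDS rule** is a conjunctive genotype condition with a guideline
  message, e.g. the warfarin starting-dose rule:

  ```
  (has some CYP2C9*1) ⊓ (has some CYP2C9*3) ⊓ (has exactly 2 rs9923231_T)
      →  "0.5–2 mg warfarin per day should be considered as a starting dose range …"
  ```

* **Inference** over a (possibly incomplete, unphased) diploid profile is
  three-valued: every allele and rule gets TRUE / FALSE / UNKNOWN, where
  the status equals the verdict under *all* / *no* / *some* completions of
  the missing genotypes. "Insufficient data" is never conflated with
  "does not apply".

* The **code** packs each marker into ⌈log₂(G+1)⌉ bits (G = number of
  unordered genotype pairs; 2 bits for a biallelic SNP, index 0 = unknown),
  maps the bit string through the base64url alphabet and embeds it as
  `http://safety-code.org/v0.2/<payload>`. A full 385-marker panel is 770
  bits ≈ 129 characters — comfortably inside QR capacity (23,648 data bits
  at version 40, level L).

* **Knowledge-base consistency** is audited by exhaustive finite-domain
  satisfiability over the diploid genotype space: unsatisfiable allele
  definitions and rules, self-contradictory necessary atoms, and duplicate
  tag sets are reported deterministically.

See `docs/methods.md` for the full account, including every convention and
its rationale.

## Worked example

The bundled knowledge base contains the CYP2C9 \*1/\*3 definitions and the
warfarin starting-dose rule. Encode a compound-heterozygote profile that is
also homozygous for rs9923231_T, then interpret the resulting code:

```
$ msc encode --kb kb.json --in profile.txt --qr code.png --out url.txt
$ cat url.txt
http://safety-code.org/v0.2/lc

$ msc interpret --kb kb.json --code "$(cat url.txt)"
Knowledge base version: v0.2
Panel markers: 5 known, 0 unknown

Allele calls:
  CYP2C9*1: TRUE
  CYP2C9*3: TRUE

Recommendations:
  [rule9] TRIGGERED: 0.5–2 mg warfarin per day should be considered as a starting dose range for a patient with this genotype according to the warfarin drug label.
```

Both CYP2C9 alleles are called present (on unphased data a \*1/\*3
compound heterozygote matches both presence classes), the VKORC1 condition
`has exactly 2 rs9923231_T` is met, and the rule fires with its label text.
The five panel genotypes fit in 10 bits, hence the two-character payload
`lc`; `code.png` holds the same URL as a QR symbol. Changing rs9923231 to
C/T un-triggers the rule; masking it yields
`[rule9] INSUFFICIENT DATA (missing: rs9923231)` instead.

Other subcommands: `msc decode` (code → genotype TSV), `msc validate-kb`
(consistency findings; exit 0 iff clean), `msc gen-fixtures` (write a
synthetic 385-marker KB plus sampled profiles in both file dialects).
Everything is equally usable as a library — see `medsafecode.__init__` for
the public API.

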