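{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "$id": "https://example.org/medsafecode/kb.schema.json",
 "title": "medsafecode knowledge base",
 "description": "Markers, star-allele (haplotype) definitions and clinical decision-support rules. Variant atoms are strings of the form '<rsid>_<nucleotide>'. This document describes the interface; validation is performed by medsafecode.kb.load_kb.",
 "type": "object",
 "required": ["version", "build", "markers", "haplotypes", "rules"],
 "properties": {
  "version": {"type": "string", "description": "Code dialect version carried in safety-code URLs, e.g. 'v0.2'."},
  "build": {"type": "string", "description": "Reference genome label, e.g. 'GRCh37'."},
  "panel_genes": {"type": "array", "items": {"type": "string"}},
  "markers": {
   "type": "array",
   "description": "Panel SNPs in code-layout order.",
   "items": {
    "type": "object",
    "required": ["rsid", "chromosome", "position", "reference", "allowed"],
    "properties": {
     "rsid": {"type": "string", "pattern": "^rs[0-9]+$"},
     "chromosome": {"type": "string", "pattern": "^([1-9]|1[0-9]|2[0-2]|X|Y|MT)$"},
     "position": {"type": "integer", "minimum": 1},
     "reference": {"type": "string", "enum": ["A", "C", "G", "T"]},
     "allowed": {
      "type": "array",
      "minItems": 2,
      "maxItems": 4,
      "uniqueItems": true,
      "items": {"type": "string", "enum": ["A", "C", "G", "T"]},
      "description": "Observable nucleotides; the first entry must equal 'reference'."
     }
    }
   }
  },
  "haplotypes": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["gene", "label", "sufficient", "necessary"],
    "properties": {
     "gene": {"type": "string"},
     "label": {"type": "string", "pattern": "^\\*.+$"},
     "sufficient": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/atom"}},
     "necessary": {"type": "array", "items": {"$ref": "#/$defs/atom"}},
     "metadata": {"type": "object"}
    }
   }
  },
  "rules": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["rule_id", "condition", "message"],
    "properties": {
     "rule_id": {"type": "string", "minLength": 1},
     "condition": {"$ref": "#/$defs/condition"},
     "message": {"type": "string", "minLength": 1},
     "source": {"type": "string"}
    }
   }
  }
 },
 "$defs": {
  "atom": {"type": "string", "pattern": "^rs[0-9]+_[ACGT]$"},
  "condition": {
   "type": "object",
   "minProperties": 1,
   "maxProperties": 1,
   "properties": {
    "has_some": {"$ref": "#/$defs/atom"},
    "has_exactly": {
     "type": "object",
     "required": ["n", "atom"],
     "properties": {
      "n": {"type": "integer", "minimum": 0, "maximum": 2},
      "atom": {"$ref": "#/$defs/atom"}
     }
    },
    "has_haplotype": {"type": "string", "pattern": "^.+\\*.+$"},
    "and": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/condition"}}
   },
   "additionalProperties": false
  }
 }
}
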