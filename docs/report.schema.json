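{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "$id": "https://example.org/medsafecode/report.schema.json",
 "title": "medsafecode interpretation report",
 "type": "object",
 "required": ["kb_version", "profile_summary", "allele_calls", "rule_matches"],
 "properties": {
  "kb_version": {"type": "string"},
  "profile_summary": {
   "type": "object",
   "required": ["known_markers", "unknown_markers"],
   "properties": {
    "known_markers": {"type": "integer", "minimum": 0},
    "unknown_markers": {"type": "integer", "minimum": 0}
   }
  },
  "allele_calls": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["gene", "label", "status", "conflict"],
    "properties": {
     "gene": {"type": "string"},
     "label": {"type": "string"},
     "status": {"enum": ["TRUE", "FALSE", "UNKNOWN"]},
     "conflict": {"type": "boolean"},
     "supporting_atoms": {"type": "array", "items": {"type": "string"}}
    }
   }
  },
  "rule_matches": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["rule_id", "status", "message"],
    "properties": {
     "rule_id": {"type": "string"},
     "status": {"enum": ["TRUE", "FALSE", "UNKNOWN"]},
     "message": {"type": "string"},
     "missing_markers": {"type": "array", "items": {"type": "string"}}
    }
   }
  }
 }
}
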