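{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "epityper run report",
  "type": "object",
  "required": [
    "version",
    "seed",
    "n_tumors",
    "n_normals",
    "n_probes",
    "selected_sites",
    "chosen_k",
    "epitype_sizes",
    "pattern_set_sizes",
    "hypermethylation_score_mean"
  ],
  "properties": {
    "version": {"type": "string"},
    "seed": {"type": "integer"},
    "n_tumors": {"type": "integer"},
    "n_normals": {"type": "integer"},
    "n_probes": {"type": "integer"},
    "selected_sites": {
      "type": "object",
      "required": ["cancer_methylated", "cancer_unmethylated", "min_count"],
      "properties": {
        "cancer_methylated": {"type": "integer"},
        "cancer_unmethylated": {"type": "integer"},
        "min_count": {"type": "integer"}
      }
    },
    "chosen_k": {"type": "integer"},
    "k_diagnostics": {"type": "object"},
    "epitype_sizes": {"type": "object"},
    "pattern_set_sizes": {"type": "object"},
    "hypermethylation_score_mean": {
      "type": "object",
      "required": ["global", "promoter_island"],
      "properties": {
        "global": {"type": "number"},
        "promoter_island": {"type": "number"}
      }
    },
    "validation_epitype_sizes": {"type": "object"}
  }
}
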