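{
  "type": "object",
  "required": ["seed", "config", "versions", "stages"],
  "properties": {
    "seed": {"type": "integer"},
    "config": {"type": "object"},
    "versions": {"type": "object"},
    "stages": {
      "type": "object",
      "required": ["annotate", "enrich", "partition", "scan", "psi"],
      "properties": {
        "annotate": {
          "type": "object",
          "required": ["n_transcripts", "n_snornas", "n_snort_calls"],
          "properties": {
            "n_transcripts": {"type": "integer"},
            "n_snornas": {"type": "integer"},
            "n_snort_calls": {"type": "integer"}
          }
        },
        "enrich": {
          "type": "object",
          "required": ["n_features", "n_targets", "alpha"],
          "properties": {
            "n_features": {"type": "integer"},
            "n_targets": {"type": "integer"},
            "alpha": {"type": "number"}
          }
        },
        "partition": {
          "type": "object",
          "required": ["counts", "percent", "median_partition"],
          "properties": {
            "counts": {"type": "object"},
            "percent": {"type": "object"},
            "median_partition": {"type": "object"}
          }
        },
        "scan": {
          "type": "object",
          "required": ["n_scanned", "n_h_and_downstream_aca", "n_plausible_pair"],
          "properties": {
            "n_scanned": {"type": "integer"},
            "n_h_and_downstream_aca": {"type": "integer"},
            "n_plausible_pair": {"type": "integer"}
          }
        },
        "psi": {
          "type": "object",
          "required": ["overlap", "sites_with_guide", "covered_sites"],
          "properties": {
            "overlap": {
              "type": "object",
              "required": ["k", "n", "K", "N", "observed_percent",
                           "expected_percent", "p_upper"]
            },
            "sites_with_guide": {"type": "integer"},
            "covered_sites": {"type": "integer"}
          }
        },
        "eclip": {
          "type": "object",
          "required": ["category_counts"],
          "properties": {"category_counts": {"type": "object"}}
        }
      }
    }
  }
}
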