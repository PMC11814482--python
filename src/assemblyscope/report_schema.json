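{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "assemblyscope pipeline report",
  "type": "object",
  "required": ["provenance", "stages"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["package", "version", "master_seed", "stage_seeds", "config", "config_hash"],
      "properties": {
        "package": {"type": "string"},
        "version": {"type": "string"},
        "master_seed": {"type": "integer"},
        "stage_seeds": {"type": "object"},
        "config": {"type": "object"},
        "config_hash": {"type": "string"}
      }
    },
    "stages": {
      "type": "object",
      "required": ["diversity", "assembly", "niche", "networks", "indicators"],
      "properties": {
        "diversity": {
          "type": "object",
          "required": ["n_otus", "n_samples", "alpha_means", "permanova", "nmds_stress"],
          "properties": {
            "n_otus": {"type": "integer"},
            "n_samples": {"type": "integer"},
            "alpha_means": {"type": "object"},
            "permanova": {"type": "object"},
            "nmds_stress": {"type": "number"}
          }
        },
        "assembly": {
          "type": "object",
          "required": ["ncm", "avd_per_group", "process_partition"],
          "properties": {
            "ncm": {"type": "object"},
            "avd_per_group": {"type": "object"},
            "process_partition": {"type": "object"}
          }
        },
        "niche": {
          "type": "object",
          "required": ["class_counts", "class_abundance_by_group"]
        },
        "networks": {
          "type": "object",
          "required": ["otu_network"]
        },
        "indicators": {
          "type": "object",
          "required": ["n_otus_tested", "n_significant"]
        }
      }
    }
  }
}
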