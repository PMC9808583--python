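{
  "nephritis_sle": {
    "labels": [
      "immune",
      "urogenital"
    ],
    "metrics": {
      "average_precision": {
        "ci_high": 1.0,
        "ci_low": 1.0,
        "mean": 1.0
      },
      "precision_at_10": {
        "ci_high": 0.5,
        "ci_low": 0.5,
        "mean": 0.5
      },
      "precision_at_3": {
        "ci_high": 1.0,
        "ci_low": 1.0,
        "mean": 1.0
      },
      "recall": {
        "ci_high": 1.0,
        "ci_low": 1.0,
        "mean": 1.0
      }
    },
    "n_index": 6,
    "n_relevant_patients": 6,
    "phenotype": "nephritis_sle"
  },
  "osteoporosis": {
    "labels": [
      "musculoskeletal",
      "nutritional"
    ],
    "metrics": {
      "average_precision": {
        "ci_high": 1.0,
        "ci_low": 1.0,
        "mean": 1.0
      },
      "precision_at_10": {
        "ci_high": 0.5,
        "ci_low": 0.5,
        "mean": 0.5
      },
      "precision_at_3": {
        "ci_high": 1.0,
        "ci_low": 1.0,
        "mean": 1.0
      },
      "recall": {
        "ci_high": 1.0,
        "ci_low": 1.0,
        "mean": 1.0
      }
    },
    "n_index": 6,
    "n_relevant_patients": 6,
    "phenotype": "osteoporosis"
  }
}
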