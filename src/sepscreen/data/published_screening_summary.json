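{
  "description": "Published summary inputs for a suspected-infection ED cohort: per-endpoint group sizes and the sensitivity/specificity of NEWS >= 5 and qSOFA >= 2, plus the cohort flow counts. Used to reconstruct the underlying 2x2 tables and re-derive PPV/NPV/accuracy.",
  "flow": {"n_suspected_infection": 886, "n_complete": 556},
  "endpoints": {
    "sepsis": {
      "n_pos": 300, "n_neg": 256,
      "news": {"sensitivity": 0.86, "specificity": 0.55},
      "qsofa": {"sensitivity": 0.34, "specificity": 0.90}
    },
    "icu": {
      "n_pos": 57, "n_neg": 499,
      "news": {"sensitivity": 0.82, "specificity": 0.35},
      "qsofa": {"sensitivity": 0.33, "specificity": 0.78}
    },
    "mortality": {
      "n_pos": 132, "n_neg": 424,
      "news": {"sensitivity": 0.88, "specificity": 0.40},
      "qsofa": {"sensitivity": 0.37, "specificity": 0.82}
    }
  }
}
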