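{
  "description": "Published summary counts and tetrachoric correlations from the Swedish register study of ADHD and eating disorders, used by the reproduction mode. Correlations and pair counts are inputs; all derived quantities are recomputed.",
  "population": {
    "n_total": 3550118,
    "n_female": 1726311,
    "n_male": 1823807,
    "birth_years": [1970, 2005]
  },
  "relative_pairs": {
    "full_sibling": 4191852,
    "maternal_half_sibling": 697763,
    "paternal_half_sibling": 829126,
    "cousin": 16347002
  },
  "quantitative_genetic_pairs": {
    "full_sister": 334433,
    "maternal_half_sister": 57036
  },
  "table1": {
    "total": {
      "n_adhd": 108443,
      "n_no_adhd": 3441675,
      "counts_adhd": {"anyED": 2887, "AN": 998, "OED": 2586, "BN": 741},
      "counts_no_adhd": {"anyED": 30030, "AN": 14217, "OED": 22962, "BN": 7090}
    },
    "female": {
      "n_adhd": 38339,
      "n_no_adhd": 1687972,
      "counts_adhd": {"anyED": 2588, "AN": 916, "OED": 2323, "BN": 709},
      "counts_no_adhd": {"anyED": 28260, "AN": 13425, "OED": 21659, "BN": 6938}
    },
    "male": {
      "n_adhd": 70104,
      "n_no_adhd": 1753703,
      "counts_adhd": {"anyED": 299, "AN": 82, "OED": 263, "BN": 32},
      "counts_no_adhd": {"anyED": 1770, "AN": 792, "OED": 1303, "BN": 152}
    }
  },
  "table2": {
    "pair_counts": {
      "ADHD": {
        "full_sister": {"both_affected": 787, "both_unaffected": 322529, "discordant": 11117},
        "maternal_half_sister": {"both_affected": 292, "both_unaffected": 52031, "discordant": 4713}
      },
      "AN": {
        "full_sister": {"both_affected": 107, "both_unaffected": 328436, "discordant": 5890},
        "maternal_half_sister": {"both_affected": 5, "both_unaffected": 56103, "discordant": 928}
      },
      "OED": {
        "full_sister": {"both_affected": 250, "both_unaffected": 324912, "discordant": 9271},
        "maternal_half_sister": {"both_affected": 19, "both_unaffected": 55133, "discordant": 1884}
      },
      "BN": {
        "full_sister": {"both_affected": 34, "both_unaffected": 331325, "discordant": 3074},
        "maternal_half_sister": {"both_affected": 4, "both_unaffected": 56461, "discordant": 571}
      }
    },
    "correlations": {
      "ADHD": {
        "full_sister": {"within": 0.41, "within_ci": [0.39, 0.42]},
        "maternal_half_sister": {"within": 0.22, "within_ci": [0.19, 0.25]}
      },
      "AN": {
        "full_sister": {"within": 0.21, "within_ci": [0.18, 0.25], "phenotypic": 0.19, "cross": 0.04},
        "maternal_half_sister": {"within": 0.03, "within_ci": [-0.10, 0.15], "phenotypic": 0.17, "cross": 0.004}
      },
      "OED": {
        "full_sister": {"within": 0.23, "within_ci": [0.20, 0.25], "phenotypic": 0.31, "cross": 0.11},
        "maternal_half_sister": {"within": 0.02, "within_ci": [-0.05, 0.10], "phenotypic": 0.28, "cross": 0.04}
      },
      "BN": {
        "full_sister": {"within": 0.20, "within_ci": [0.16, 0.24], "phenotypic": 0.28, "cross": 0.07},
        "maternal_half_sister": {"within": 0.13, "within_ci": [-0.02, 0.27], "phenotypic": 0.23, "cross": 0.07}
      }
    }
  }
}
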