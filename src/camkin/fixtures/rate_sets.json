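{
  "S1": {
    "our_fits": {
      "source_label": "our fits",
      "log10_forward": {"k1": 8.10, "k3": 4.00},
      "log10_kd": {"KD1": -9.00, "KD2": -9.00}
    },
    "kim": {
      "source_label": "Kim et al.",
      "log10_forward": {"k1": 3.60, "k3": 5.0},
      "log10_kd": {"KD1": -5.69, "KD2": -4.96}
    }
  },
  "S2": {
    "our_fits": {
      "source_label": "our fits",
      "log10_forward": {"k1": 8.13, "k3": 2.25, "k5": 4.52},
      "log10_kd": {"KD1": -9.00, "KD2": -9.00, "KD3": -6.40}
    },
    "hayer_bhalla": {
      "source_label": "Hayer and Bhalla",
      "log10_forward": {"k1": 4.86, "k3": 3.56, "k5": 2.67},
      "log10_kd": {"KD1": -6.00, "KD2": -5.55, "KD3": -4.68}
    }
  },
  "S3": {
    "our_fits": {
      "source_label": "our fits",
      "log10_forward": {"k1": 5.41, "k3": 2.36, "k5": 4.33, "k7": 5.04},
      "log10_kd": {"KD1": -4.87, "KD2": -7.83, "KD3": -6.40, "KD4": -6.19}
    },
    "shifman": {
      "source_label": "Shifman et al. (K_D only; nominal on-rates)",
      "log10_forward": {"k1": 5.0, "k3": 5.0, "k5": 5.0, "k7": 5.0},
      "log10_kd": {"KD1": -5.10, "KD2": -5.77, "KD3": -4.46, "KD4": -5.05}
    }
  },
  "S4": {
    "our_fits": {
      "source_label": "our fits (S4)",
      "log10_forward": {"k1": 4.33, "k3": 5.98, "k5": 7.03, "k7": 6.29},
      "log10_kd": {"KD1": -5.56, "KD2": -6.01, "KD3": -4.13, "KD4": -5.73}
    },
    "pepke": {
      "source_label": "Pepke et al.",
      "log10_forward": {"k1": 3.60, "k3": 4.00, "k5": 5.0, "k7": 5.18},
      "log10_kd": {"KD1": -5.00, "KD2": -6.03, "KD3": -4.60, "KD4": -5.30}
    }
  },
  "S5": {
    "our_fits": {
      "source_label": "our fits",
      "log10_forward": {"k1": 4.50, "k3": 4.08, "k5": 5.69, "k7": 6.32},
      "log10_kd": {"KD1": -5.43, "KD2": -5.84, "KD3": -4.00, "KD4": -5.30}
    },
    "faas": {
      "source_label": "Faas et al.",
      "log10_forward": {"k1": 4.90, "k3": 4.40, "k5": 5.90, "k7": 7.50},
      "log10_kd": {"KD1": -4.60, "KD2": -6.60, "KD3": -3.70, "KD4": -6.10}
    },
    "pepke": {
      "source_label": "Pepke et al. (intrinsic-site convention)",
      "log10_forward": {"k1": 3.60, "k3": 4.00, "k5": 5.0, "k7": 5.18},
      "log10_kd": {"KD1": -5.00, "KD2": -6.03, "KD3": -4.60, "KD4": -5.30},
      "double_forward": ["k1", "k5"],
      "double_reverse": ["k4", "k8"]
    }
  },
  "S6": {
    "our_fits": {
      "source_label": "our fits",
      "log10_forward": {
        "k1c": 4.23, "k3c": 4.16, "k5c": 5.22, "k7c": 2.31,
        "k1n": 3.03, "k3n": 6.65, "k5n": 5.22, "k7n": 7.58
      },
      "log10_kd": {
        "KD1c": -5.40, "KD2c": -4.38, "KD3c": -5.38, "KD4c": -6.40,
        "KD1n": -4.06, "KD2n": -5.20, "KD3n": -2.88, "KD4n": -6.38
      }
    },
    "byrne": {
      "source_label": "Byrne et al.",
      "log10_forward": {
        "k1c": 5.44, "k3c": 5.44, "k5c": 3.57, "k7c": 5.07,
        "k1n": 5.44, "k3n": 5.44, "k5n": 5.71, "k7n": 5.70
      },
      "log10_kd": {
        "KD1c": -4.73, "KD2c": -3.94, "KD3c": -6.42, "KD4c": -7.22,
        "KD1n": -4.48, "KD2n": -5.46, "KD3n": -3.64, "KD4n": -6.31
      }
    }
  }
}
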