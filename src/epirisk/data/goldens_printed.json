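{
  "comment": "Published reference values, stored verbatim at their printed precision. memberships/stm: 4 decimals; stable_state/baseline_safety/control_t1: 3 decimals. STM rows 3 and 4 are stored de-interleaved (the source prints them interleaved column-wise).",
  "rounding": {"memberships": 4, "stm": 4, "stable_state": 3, "control": 3},
  "memberships": {
    "t0": {
      "a1": [0.0000, 0.5000, 0.3333, 0.1667],
      "a2": [0.3333, 0.5556, 0.1111, 0.0000],
      "a3": [0.5000, 0.5000, 0.0000, 0.0000],
      "a4": [0.0000, 0.5000, 0.3333, 0.1667],
      "a5": [0.0000, 0.3333, 0.3333, 0.3333],
      "a6": [0.0000, 0.5000, 0.3333, 0.1667],
      "a7": [0.1667, 0.6667, 0.1667, 0.0000],
      "a8": [0.1667, 0.6667, 0.1667, 0.0000],
      "a9": [0.1667, 0.6667, 0.1667, 0.0000]
    },
    "t1": {
      "a1": [0.0000, 0.0000, 0.2500, 0.7500],
      "a2": [0.0000, 0.5000, 0.3333, 0.1667],
      "a3": [0.1667, 0.6667, 0.1667, 0.0000],
      "a4": [0.0000, 0.0000, 0.2500, 0.7500],
      "a5": [0.0000, 0.0000, 0.0000, 1.0000],
      "a6": [0.0000, 0.0000, 0.2500, 0.7500],
      "a7": [0.0000, 0.0000, 0.2500, 0.7500],
      "a8": [0.0000, 0.5000, 0.3333, 0.1667],
      "a9": [0.0000, 0.7500, 0.2500, 0.0000]
    },
    "t2": {
      "a1": [0.0000, 0.0000, 0.2500, 0.7500],
      "a2": [0.0000, 0.1667, 0.3333, 0.5000],
      "a3": [0.1667, 0.6667, 0.1667, 0.0000],
      "a4": [0.0000, 0.0000, 0.0000, 1.0000],
      "a5": [0.0000, 0.0000, 0.0000, 1.0000],
      "a6": [0.0000, 0.0000, 0.0000, 1.0000],
      "a7": [0.0000, 0.0000, 0.0000, 1.0000],
      "a8": [0.0000, 0.3333, 0.3333, 0.3333],
      "a9": [0.0000, 0.7500, 0.2500, 0.0000]
    }
  },
  "stm": {
    "t0": [
      [0.2667, 0.6111, 0.1222, 0.0000],
      [0.1482, 0.5432, 0.2160, 0.0926],
      [0.1042, 0.5486, 0.2430, 0.1042],
      [0.0000, 0.4583, 0.3333, 0.2084]
    ],
    "t1": [
      [0.1667, 0.6666, 0.1667, 0.0000],
      [0.0417, 0.6042, 0.2708, 0.0833],
      [0.0208, 0.3021, 0.2604, 0.4167],
      [0.0000, 0.1429, 0.2381, 0.6191]
    ],
    "t2": [
      [0.1667, 0.6666, 0.1667, 0.0000],
      [0.0417, 0.4792, 0.2708, 0.2083],
      [0.0333, 0.3833, 0.2667, 0.3167],
      [0.0000, 0.0714, 0.1309, 0.7976]
    ]
  },
  "stable_state": {
    "t0": [0.142, 0.546, 0.220, 0.093],
    "t1": [0.025, 0.364, 0.254, 0.357],
    "t2": [0.020, 0.241, 0.191, 0.548]
  },
  "baseline_safety": {"t0": 0.688, "t1": 0.389, "t2": 0.261},
  "control_t1": {
    "none": {"stable_state": [0.025, 0.364, 0.254, 0.357], "safety": 0.389},
    "a1":   {"stable_state": [0.022, 0.363, 0.292, 0.323], "safety": 0.385},
    "a2":   {"stable_state": [0.049, 0.380, 0.226, 0.345], "safety": 0.429},
    "a3":   {"stable_state": [0.085, 0.340, 0.222, 0.353], "safety": 0.425},
    "a4":   {"stable_state": [0.022, 0.363, 0.292, 0.323], "safety": 0.385},
    "a5":   {"stable_state": [0.024, 0.355, 0.286, 0.335], "safety": 0.379},
    "a6":   {"stable_state": [0.022, 0.363, 0.292, 0.323], "safety": 0.385},
    "a7":   {"stable_state": [0.022, 0.363, 0.292, 0.323], "safety": 0.385},
    "a8":   {"stable_state": [0.049, 0.380, 0.226, 0.345], "safety": 0.429},
    "a9":   {"stable_state": [0.055, 0.362, 0.224, 0.359], "safety": 0.417}
  },
  "effective_controls": {
    "t1": ["a2", "a3", "a8", "a9"]
  },
  "qualitative": {
    "t0": {
      "effective": ["a1", "a2", "a3", "a4", "a5", "a6", "a7", "a8", "a9"],
      "top": ["a5"]
    },
    "t1": {
      "effective": ["a2", "a3", "a8", "a9"],
      "top": ["a2", "a8"]
    },
    "t2": {
      "effective": ["a1", "a2", "a3", "a4", "a6", "a7", "a9"],
      "ineffective": ["a5", "a8"],
      "top": ["a2", "a1"]
    }
  }
}
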