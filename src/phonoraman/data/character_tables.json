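{
  "version": 1,
  "comment": "Factor-group character tables for the 1-D-irrep point groups shipped with phonoraman. Classes carry the (det, trace) signature of the Cartesian rotation part and an optional axis role for groups with several same-signature classes. raman/ir flags follow quadratic vs linear basis functions.",
  "groups": {
    "C1": {
      "classes": [{"label": "E", "det": 1, "trace": 3}],
      "irreps": [
        {"name": "A", "characters": [1], "raman": true, "ir": true}
      ]
    },
    "Ci": {
      "classes": [
        {"label": "E", "det": 1, "trace": 3},
        {"label": "i", "det": -1, "trace": -3}
      ],
      "irreps": [
        {"name": "Ag", "characters": [1, 1], "raman": true, "ir": false},
        {"name": "Au", "characters": [1, -1], "raman": false, "ir": true}
      ]
    },
    "Cs": {
      "classes": [
        {"label": "E", "det": 1, "trace": 3},
        {"label": "sigma", "det": -1, "trace": 1}
      ],
      "irreps": [
        {"name": "A'", "characters": [1, 1], "raman": true, "ir": true},
        {"name": "A''", "characters": [1, -1], "raman": true, "ir": true}
      ]
    },
    "C2": {
      "classes": [
        {"label": "E", "det": 1, "trace": 3},
        {"label": "C2", "det": 1, "trace": -1}
      ],
      "irreps": [
        {"name": "A", "characters": [1, 1], "raman": true, "ir": true},
        {"name": "B", "characters": [1, -1], "raman": true, "ir": true}
      ]
    },
    "C2h": {
      "classes": [
        {"label": "E", "det": 1, "trace": 3},
        {"label": "C2", "det": 1, "trace": -1},
        {"label": "i", "det": -1, "trace": -3},
        {"label": "sigma_h", "det": -1, "trace": 1}
      ],
      "irreps": [
        {"name": "Ag", "characters": [1, 1, 1, 1], "raman": true, "ir": false},
        {"name": "Bg", "characters": [1, -1, 1, -1], "raman": true, "ir": false},
        {"name": "Au", "characters": [1, 1, -1, -1], "raman": false, "ir": true},
        {"name": "Bu", "characters": [1, -1, -1, 1], "raman": false, "ir": true}
      ]
    },
    "C2v": {
      "classes": [
        {"label": "E", "det": 1, "trace": 3},
        {"label": "C2", "det": 1, "trace": -1},
        {"label": "sigma_v", "det": -1, "trace": 1, "axis_rank": 0},
        {"label": "sigma_v'", "det": -1, "trace": 1, "axis_rank": 1}
      ],
      "irreps": [
        {"name": "A1", "characters": [1, 1, 1, 1], "raman": true, "ir": true},
        {"name": "A2", "characters": [1, 1, -1, -1], "raman": true, "ir": false},
        {"name": "B1", "characters": [1, -1, 1, -1], "raman": true, "ir": true},
        {"name": "B2", "characters": [1, -1, -1, 1], "raman": true, "ir": true}
      ]
    },
    "D2": {
      "classes": [
        {"label": "E", "det": 1, "trace": 3},
        {"label": "C2z", "det": 1, "trace": -1, "axis_rank": 0},
        {"label": "C2y", "det": 1, "trace": -1, "axis_rank": 1},
        {"label": "C2x", "det": 1, "trace": -1, "axis_rank": 2}
      ],
      "irreps": [
        {"name": "A", "characters": [1, 1, 1, 1], "raman": true, "ir": false},
        {"name": "B1", "characters": [1, 1, -1, -1], "raman": true, "ir": true},
        {"name": "B2", "characters": [1, -1, 1, -1], "raman": true, "ir": true},
        {"name": "B3", "characters": [1, -1, -1, 1], "raman": true, "ir": true}
      ]
    },
    "D2h": {
      "classes": [
        {"label": "E", "det": 1, "trace": 3},
        {"label": "C2z", "det": 1, "trace": -1, "axis_rank": 0},
        {"label": "C2y", "det": 1, "trace": -1, "axis_rank": 1},
        {"label": "C2x", "det": 1, "trace": -1, "axis_rank": 2},
        {"label": "i", "det": -1, "trace": -3},
        {"label": "sigma_xy", "det": -1, "trace": 1, "axis_rank": 0},
        {"label": "sigma_xz", "det": -1, "trace": 1, "axis_rank": 1},
        {"label": "sigma_yz", "det": -1, "trace": 1, "axis_rank": 2}
      ],
      "irreps": [
        {"name": "Ag", "characters": [1, 1, 1, 1, 1, 1, 1, 1], "raman": true, "ir": false},
        {"name": "B1g", "characters": [1, 1, -1, -1, 1, 1, -1, -1], "raman": true, "ir": false},
        {"name": "B2g", "characters": [1, -1, 1, -1, 1, -1, 1, -1], "raman": true, "ir": false},
        {"name": "B3g", "characters": [1, -1, -1, 1, 1, -1, -1, 1], "raman": true, "ir": false},
        {"name": "Au", "characters": [1, 1, 1, 1, -1, -1, -1, -1], "raman": false, "ir": false},
        {"name": "B1u", "characters": [1, 1, -1, -1, -1, -1, 1, 1], "raman": false, "ir": true},
        {"name": "B2u", "characters": [1, -1, 1, -1, -1, 1, -1, 1], "raman": false, "ir": true},
        {"name": "B3u", "characters": [1, -1, -1, 1, -1, 1, 1, -1], "raman": false, "ir": true}
      ]
    }
  }
}
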