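{
  "description": "Published thermodynamic cycle closures (kcal/mol) for the 15-ligand ACK1 inhibitor perturbation map, 12 cycles x 5 set-up protocols; null marks cycles not run under a protocol.",
  "units": "kcal/mol",
  "threshold": 0.8,
  "protocols": ["A", "B", "C", "D", "E"],
  "cycles": [
    {"cycle": ["3", "2", "5", "6"],
     "closures": {"A": [0.6, 0.3], "B": [0.0, 0.3], "C": [0.6, 0.6], "D": [0.2, 0.4], "E": [0.8, 0.3]}},
    {"cycle": ["3", "2", "5"],
     "closures": {"A": [0.2, 0.2], "B": [-0.4, 0.2], "C": [0.7, 0.5], "D": [0.0, 0.1], "E": [0.5, 0.3]}},
    {"cycle": ["2", "6", "5"],
     "closures": {"A": [-0.8, 0.4], "B": [0.0, 0.3], "C": [0.0, 0.3], "D": [-0.2, 0.3], "E": [-0.7, 0.8]}},
    {"cycle": ["3", "5", "6"],
     "closures": {"A": [0.4, 0.2], "B": [0.4, 0.2], "C": [-0.1, 0.4], "D": [0.2, 0.4], "E": [0.4, 0.1]}},
    {"cycle": ["3", "6", "2"],
     "closures": {"A": [0.2, 0.4], "B": [0.1, 0.3], "C": [-0.6, 0.5], "D": [0.0, 0.2], "E": [-0.1, 0.9]}},
    {"cycle": ["3", "4", "7", "6"],
     "closures": {"A": [1.0, 0.4], "B": [0.3, 0.4], "C": [1.6, 0.4], "D": [0.2, 0.4], "E": [0.3, 0.7]}},
    {"cycle": ["3", "7", "6"],
     "closures": {"A": [0.2, 0.4], "B": [0.1, 0.3], "C": [0.9, 0.7], "D": [0.2, 0.3], "E": [-0.2, 0.9]}},
    {"cycle": ["4", "6", "7"],
     "closures": {"A": [0.9, 0.6], "B": [0.0, 0.3], "C": [-1.1, 0.5], "D": [0.2, 0.3], "E": [-0.2, 0.8]}},
    {"cycle": ["3", "4", "7"],
     "closures": {"A": [0.8, 0.4], "B": [0.2, 0.4], "C": [0.7, 0.7], "D": [0.0, 0.2], "E": [0.5, 0.5]}},
    {"cycle": ["3", "4", "6"],
     "closures": {"A": [1.9, 0.4], "B": [0.3, 0.2], "C": [0.5, 0.5], "D": [0.2, 0.4], "E": [0.1, 0.4]}},
    {"cycle": ["45", "16", "44"],
     "closures": {"A": [-2.0, 1.0], "B": [-3.0, 1.0], "C": [-2.0, 1.0], "D": [-1.8, 0.9], "E": null}},
    {"cycle": ["38", "39", "35", "36"],
     "closures": {"A": [0.6, 0.5], "B": [0.6, 0.5], "C": [0.2, 0.3], "D": [0.2, 0.3], "E": null}}
  ]
}
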