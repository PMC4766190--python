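{
  "name": "yeast_polarization",
  "places": [
    {"id": "L", "description": "pheromone ligand"},
    {"id": "R", "description": "pheromone receptor"},
    {"id": "RL", "description": "receptor-ligand complex"},
    {"id": "G", "description": "heterotrimeric G-protein"},
    {"id": "Gbg", "description": "G-protein beta-gamma subunit"},
    {"id": "Ga", "description": "activated G-protein alpha subunit"},
    {"id": "Gd", "description": "dephosphorylated G-protein alpha subunit"}
  ],
  "transitions": [
    {"id": "r1", "rate_law": "mass_action", "parameter": 0.38},
    {"id": "r2", "rate_law": "mass_action", "parameter": 0.04},
    {"id": "r3", "rate_law": "mass_action", "parameter": 0.082},
    {"id": "r4", "rate_law": "mass_action", "parameter": 0.12},
    {"id": "r5", "rate_law": "mass_action", "parameter": 0.021},
    {"id": "r6", "rate_law": "mass_action", "parameter": 0.1},
    {"id": "r7", "rate_law": "mass_action", "parameter": 0.005},
    {"id": "r8", "rate_law": "mass_action", "parameter": 13.21}
  ],
  "arcs": [
    {"from": "r1", "to": "R", "weight": 1},
    {"from": "R", "to": "r2", "weight": 1},
    {"from": "L", "to": "r3", "weight": 1},
    {"from": "R", "to": "r3", "weight": 1},
    {"from": "r3", "to": "L", "weight": 1},
    {"from": "r3", "to": "RL", "weight": 1},
    {"from": "RL", "to": "r4", "weight": 1},
    {"from": "r4", "to": "R", "weight": 1},
    {"from": "RL", "to": "r5", "weight": 1},
    {"from": "G", "to": "r5", "weight": 1},
    {"from": "r5", "to": "Ga", "weight": 1},
    {"from": "r5", "to": "Gbg", "weight": 1},
    {"from": "Ga", "to": "r6", "weight": 1},
    {"from": "r6", "to": "Gd", "weight": 1},
    {"from": "Gd", "to": "r7", "weight": 1},
    {"from": "Gbg", "to": "r7", "weight": 1},
    {"from": "r7", "to": "G", "weight": 1},
    {"from": "r8", "to": "RL", "weight": 1}
  ],
  "initial_marking": {"L": 4, "R": 500, "RL": 110, "G": 300, "Gbg": 20, "Ga": 2, "Gd": 90}
}
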