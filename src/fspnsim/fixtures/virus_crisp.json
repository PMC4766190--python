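{
  "name": "virus_crisp",
  "places": [
    {"id": "Uninfected_cells", "description": "healthy host cells"},
    {"id": "Infected_cells", "description": "virus-infected cells"},
    {"id": "Virus", "description": "free virions"}
  ],
  "transitions": [
    {"id": "Cell_growth", "rate_law": "constant", "parameter": 1.0},
    {"id": "UCell_death", "rate_law": "mass_action", "parameter": 0.1},
    {"id": "Infection", "rate_law": "mass_action", "parameter": 1.0},
    {"id": "Virus_release", "rate_law": "mass_action", "parameter": 1.0},
    {"id": "ICell_death", "rate_law": "mass_action", "parameter": 0.5},
    {"id": "Degradation", "rate_law": "mass_action", "parameter": 0.1}
  ],
  "arcs": [
    {"from": "Cell_growth", "to": "Uninfected_cells", "weight": 1},
    {"from": "Uninfected_cells", "to": "UCell_death", "weight": 1},
    {"from": "Uninfected_cells", "to": "Infection", "weight": 1},
    {"from": "Virus", "to": "Infection", "weight": 1},
    {"from": "Infection", "to": "Infected_cells", "weight": 1},
    {"from": "Infected_cells", "to": "Virus_release", "weight": 1},
    {"from": "Virus_release", "to": "Infected_cells", "weight": 1},
    {"from": "Virus_release", "to": "Virus", "weight": 10},
    {"from": "Infected_cells", "to": "ICell_death", "weight": 1},
    {"from": "Virus", "to": "Degradation", "weight": 1}
  ],
  "initial_marking": {"Uninfected_cells": 10, "Infected_cells": 0, "Virus": 5}
}
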