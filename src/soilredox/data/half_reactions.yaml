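# Half-reaction registry: terminal electron acceptors of an anaerobic,
# PCP-spiked flooded soil. `electrons_per_mole` is the electron-equivalent
# bookkeeping value (eeq per mole of compound produced or consumed);
# `electrons_transferred` is the electron count appearing in the written
# half reaction (it differs from the eeq value only for acetoclastic
# methanogenesis, a disproportionation with no free electrons).
# Charges are per side: oxidized species, and reduced side including
# byproduct ions, so that q_ox + protons - e = q_red can be machine-checked.
ferrous_iron:
  oxidized_species: "Fe3+"
  reduced_species: "Fe2+"
  electrons_per_mole: 1
  electrons_transferred: 1
  protons: 0
  charge_oxidized: 3
  charge_reduced: 2
  reference_note: "Fe3+ + e- = Fe2+"
sulfide:
  oxidized_species: "SO4^2-"
  reduced_species: "HS-"
  electrons_per_mole: 8
  electrons_transferred: 8
  protons: 9
  charge_oxidized: -2
  charge_reduced: -1
  reference_note: "SO4^2- + 9H+ + 8e- = HS- + 4H2O"
methane_acetoclastic:
  oxidized_species: "CH3COOH"
  reduced_species: "CH4"
  electrons_per_mole: 8
  electrons_transferred: 0
  protons: 0
  charge_oxidized: 0
  charge_reduced: 0
  reference_note: "CH3COOH = CH4 + CO2 (disproportionation; 8 eeq per mol CH4)"
methane_hydrogenotrophic:
  oxidized_species: "CO2"
  reduced_species: "CH4"
  electrons_per_mole: 8
  electrons_transferred: 8
  protons: 8
  charge_oxidized: 0
  charge_reduced: 0
  reference_note: "CO2 + 8H+ + 8e- = CH4 + 2H2O"
TeCP:
  oxidized_species: "C6Cl5OH"
  reduced_species: "C6HCl4OH"
  electrons_per_mole: 2
  electrons_transferred: 2
  protons: 1
  charge_oxidized: 0
  charge_reduced: -1
  reference_note: "C6Cl5OH + H+ + 2e- = C6HCl4OH + Cl-"
TCP:
  oxidized_species: "C6Cl5OH"
  reduced_species: "C6H2Cl3OH"
  electrons_per_mole: 4
  electrons_transferred: 4
  protons: 2
  charge_oxidized: 0
  charge_reduced: -2
  reference_note: "C6Cl5OH + 2H+ + 4e- = C6H2Cl3OH + 2Cl-"
DCP:
  oxidized_species: "C6Cl5OH"
  reduced_species: "C6H3Cl2OH"
  electrons_per_mole: 6
  electrons_transferred: 6
  protons: 3
  charge_oxidized: 0
  charge_reduced: -3
  reference_note: "C6Cl5OH + 3H+ + 6e- = C6H3Cl2OH + 3Cl- (ladder extension to 3,5-DCP)"
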