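"""Electron ledger of a single incubation bottle.

Builds one biotic biochar-amended bottle from reported-style endpoint
concentrations, subtracts the sterile baseline, and prints the electron
equivalents each reduction process consumed.
"""

from soilredox import BottleGeometry, IncubationEndpoint, TreatmentLabel
from soilredox.budget import compute_ledger

# endpoint chemistry of the bottle at day 120
bottle = IncubationEndpoint(
    label=TreatmentLabel("biotic", "biochar", 1),
    fe2=11.7,       # mg/g HCl-extractable Fe(II)
    sulfate=0.34,   # mg/g, down from the 0.74 sterile baseline
    ch4=200.0,      # permil of headspace
    pcp=8.0,        # ug/g residual of the 20 ug/g spike
    tecp=10.0,      # ug/g accumulated tetrachlorophenol
    tcp=0.5,        # ug/g accumulated trichlorophenol
)

# sterile abiotic means for the same amendment define the baseline
baselines = {"fe2": 5.0, "sulfate": 0.74}

ledger = compute_ledger(bottle, baselines, BottleGeometry())
print(f"Fe(III) reduction   : {ledger.e_fe:8.1f} umol e-")
print(f"sulfate reduction   : {ledger.e_so4:8.1f} umol e-")
print(f"PCP dechlorination  : {ledger.e_dechlor:8.2f} umol e-")
print(f"methanogenesis      : {ledger.e_ch4:8.1f} umol e-")
print(f"total               : {ledger.e_total:8.1f} umol e-")
# Each line is the micromoles of electrons that flowed to that terminal
# electron acceptor in this bottle; iron and methane dominate, while
# dechlorination receives a vanishing share of the donor pool.
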