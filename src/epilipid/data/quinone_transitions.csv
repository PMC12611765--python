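name,precursor_formula,precursor_adduct,product_formula,product_adduct,collision_energy,expected_rt_min,electron_convention
CoQ10,C59H90O4,[M+NH4]+,C10H12O4,[M+H]+,15,22.4,proton
CoQ10H2,C59H92O4,[M+NH4]+,C10H12O4,[M+H]+,15,22.1,proton
CoQ10-d6,C59H84D6O4,[M+NH4]+,C10H6D6O4,[M+H]+,15,22.4,hydrogen
CoQ9,C54H82O4,[M+NH4]+,C10H12O4,[M+H]+,15,21.4,proton
CoQ9H2,C54H84O4,[M+NH4]+,C10H12O4,[M+H]+,15,21.1,proton
CoQ8,C49H74O4,[M+NH4]+,C10H12O4,[M+H]+,15,20.2,proton
vitamin K1,C31H46O2,[M+H]+,C12H10O2,[M+H]+,25,17.5,proton
MK-4,C31H40O2,[M+H]+,C12H10O2,[M+H]+,25,14.8,proton
alpha-tocopherol,C29H50O2,[M+H]+,C10H12O2,[M+H]+,20,13.2,proton
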