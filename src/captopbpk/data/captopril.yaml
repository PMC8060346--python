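# Captopril drug-specific model input parameters.
# Physicochemistry, first-order absorption, minimal-PBPK distribution
# (single adjusting compartment) and empirical clearances for a healthy
# adult. Vss is stored at the higher-precision value 0.267 L/kg used by the
# distribution model (the display table rounds it to 0.26).
molecular_weight: 217.29   # g/mol
logP: 0.34                 # octanol-water log partition coefficient
pKa: 4.02
ionization_class: monoprotic_acid
ka: 1.75                   # 1/h, first-order absorption rate constant
tlag: 0.2                  # h, absorption lag time
fa: 0.7                    # fraction absorbed
kin: 0.25                  # 1/h, central -> single adjusting compartment
kout: 0.25                 # 1/h, single adjusting compartment -> central
bp_ratio: 1.0              # blood:plasma concentration ratio
fu: 0.73                   # fraction unbound in plasma
vss_per_kg: 0.267          # L/kg, steady-state volume of distribution
cl_iv: 49.5                # L/h, total systemic plasma clearance
cl_r: 22.2                 # L/h, renal plasma clearance
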