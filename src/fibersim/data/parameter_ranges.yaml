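# Biologically relevant ranges for the seven model parameters (SI units).
# The reference model uses the geometric mean of each range's limits.
parameters:
  Lr:
    min: 5.0e-9
    max: 5.0e-6
    unit: "Pa^-1 s^-1"
    meaning: "normalized hydraulic conductivity of the plasma membrane"
    source: "parenchyma cells of corn leaves; Chara algae, onion, pea"
  mu:
    min: 1.35e-26
    max: 3.3e-19
    unit: "m3 Pa^-1 s^-1"
    meaning: "total plasmodesmal permeability (open channels)"
    source: "estimated from plasmodesma channel geometries"
  alpha:
    min: 8.3e+1
    max: 1.67e+2
    unit: "Pa s^-1"
    meaning: "normalized solute source rate"
    source: "estimated from cotton fiber osmolyte accumulation"
  pi_seed:
    min: 9.9e+5
    max: 1.29e+6
    unit: "Pa"
    meaning: "osmotic pressure of the seed proper"
    source: "cotton pressure-probe measurements"
  P_seed:
    min: 7.0e+4
    max: 1.8e+5
    unit: "Pa"
    meaning: "turgor pressure of the seed"
    source: "cotton pressure-probe measurements"
  Y:
    min: 6.0e+4
    max: 2.0e+5
    unit: "Pa"
    meaning: "Lockhart yield turgor threshold"
    source: "assuming fiber turgor above yield"
  phi:
    min: 1.1e-12
    max: 2.5e-11
    unit: "Pa^-1 s^-1"
    meaning: "cell wall extensibility"
    source: "growing pea stems"
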