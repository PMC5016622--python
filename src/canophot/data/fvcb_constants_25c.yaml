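# FvCB kinetic constants at 25 degrees C, pressure-based units (Pa).
Kc: 40.4          # Michaelis-Menten constant of Rubisco for CO2 [Pa]
Ko: 24800.0       # Michaelis-Menten constant of Rubisco for O2 [Pa]
O: 20500.0        # oxygen partial pressure [Pa]
gamma: 4.4        # CO2 compensation point of net photosynthesis [Pa]
gamma_star: 3.69  # compensation point absent mitochondrial respiration [Pa]
f: 0.15           # spectral correction factor [-]
respiration_coefficient: 0.0089  # Rl/Vl for the fixed-coefficient rule [-]
theta_range: [0.68, 0.83]        # observed curvature range of J(I) [-]
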