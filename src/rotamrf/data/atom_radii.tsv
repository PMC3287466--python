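# Interaction radii (Å) by element for the piecewise repulsive energy.
# Defaults in the SCWRL hard-sphere tradition; override via EnergyParams.
# element	radius_A
C	1.60
N	1.30
O	1.30
S	1.70
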