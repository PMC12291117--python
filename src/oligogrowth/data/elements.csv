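# element,mass_da,vdw_radius_A  (Bondi radii; masses IUPAC 2021 rounded)
H,1.008,1.20
C,12.011,1.70
N,14.007,1.55
O,15.999,1.52
S,32.06,1.80
P,30.974,1.80
F,18.998,1.47
CL,35.45,1.75
BR,79.904,1.85
I,126.904,1.98
SE,78.971,1.90
FE,55.845,2.00
ZN,65.38,2.10
MG,24.305,1.73
CA,40.078,2.31
NA,22.990,2.27
K,39.098,2.75
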