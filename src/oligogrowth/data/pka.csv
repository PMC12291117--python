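# site,pka  (intrinsic model values)
ASP,3.65
GLU,4.25
CTER,3.55
HIS,6.0
LYS,10.4
ARG,12.5
NTER,8.0
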