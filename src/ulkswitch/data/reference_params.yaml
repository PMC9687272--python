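# Reference rate constants of the mTORC1-ULK1-PP2A triangle (1/min and
# 1/(conc*min); totals normalized to 1 under physiological conditions).
# This set is the generator truth for all packaged synthetic densitometry
# series.  It was designed once to reproduce the qualitative behaviour of
# the switch: bistability at physiological totals with the resting cell in
# the non-autophagy state, collapse to a single autophagy state under
# rapamycin (mTORT = 0.1) with the ULK1/PP2A activation developing after
# ~30 min, retention of both stable states under partial PP2A loss
# (PP2AT = 0.3), and the combined-perturbation outcomes of ULK1/PP2A
# silencing under mTORC1 inhibition.  See docs/methods.md.
ka_m: 0.01
ki_m: 0.001
ka_u: 0.0005
ki_u: 0.01
ka_p: 0.0003
ki_p: 0.12
k_a: 0.2
k_b: 0.1
k_c: 0.4
k_d: 0.25
k_e: 0.1
k_f: 1.0
mTORT: 1.0
ULK1T: 1.0
PP2AT: 1.0
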