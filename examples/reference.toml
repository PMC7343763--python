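# Packaged reference parameter set (already normalized by k4).
# Mode I configuration: k3 = 5; switch to k3 = 1.5 for Mode II.
k1 = 2.1
k2 = 1.0
k3 = 5.0
k4 = 1.0
kon = 10.0
koff = 10.0
a = 1.0
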