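# DPD repulsion parameters a_ij (reduced units) for simulations with
# water, PLA and the Pam lipopeptides. Lower-triangular block; the column
# order equals the row order.
species G W F C S K LA
G   78
W   99.4  78
F   26.1  91.3  78
C   26.0  82.6  28.5  78
S   28.9  61.4  31.8  26.1  78
K   161.3 26.7  157.3 134.6 101.3 78
LA  25.4  91.3  25.1  27.2  30.3  154.3 78
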