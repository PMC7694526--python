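# DPD repulsion parameters a_ij (reduced units) for simulations with
# water, PLA and vitamin E. Lower-triangular block; the column order
# equals the row order.
species W CHR C5 LA
W    78
CHR  169.6 78
C5   115.0 25.9  78
LA   91.3  25.0  25.3  78
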