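# NUC.4.4 substitution matrix (dna)
     A    C    G    T    N
A    5   -4   -4   -4   -2
C   -4    5   -4   -4   -2
G   -4   -4    5   -4   -2
T   -4   -4   -4    5   -2
N   -2   -2   -2   -2   -1
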