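# BLOSUM80 substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    7   -1   -3   -2   -4    0   -3   -3   -1   -3   -2   -3   -1   -2   -3    2    0   -1   -5   -4   -1
C   -1   13   -7   -7   -4   -6   -7   -2   -6   -3   -3   -5   -6   -5   -6   -2   -2   -2   -5   -5   -4
D   -3   -7   10    2   -6   -3   -2   -7   -2   -7   -6    2   -3   -1   -3   -1   -2   -6   -8   -6   -3
E   -2   -7    2    8   -6   -4    0   -6    1   -6   -4   -1   -2    3   -1   -1   -2   -4   -6   -5   -2
F   -4   -4   -6   -6   10   -6   -2   -1   -5    0    0   -6   -6   -5   -5   -4   -4   -2    0    4   -3
G    0   -6   -3   -4   -6    9   -4   -7   -3   -7   -5   -1   -5   -4   -4   -1   -3   -6   -6   -6   -3
H   -3   -7   -2    0   -2   -4   12   -6   -1   -5   -4    1   -4    1    0   -2   -3   -5   -4    3   -2
I   -3   -2   -7   -6   -1   -7   -6    7   -5    2    2   -6   -5   -5   -5   -4   -2    4   -5   -3   -2
K   -1   -6   -2    1   -5   -3   -1   -5    8   -4   -3    0   -2    2    3   -1   -1   -4   -6   -4   -2
L   -3   -3   -7   -6    0   -7   -5    2   -4    6    3   -6   -5   -4   -4   -4   -3    1   -4   -2   -2
M   -2   -3   -6   -4    0   -5   -4    2   -3    3    9   -4   -4   -1   -3   -3   -1    1   -3   -3   -2
N   -3   -5    2   -1   -6   -1    1   -6    0   -6   -4    9   -4    0   -1    1    0   -5   -7   -4   -2
P   -1   -6   -3   -2   -6   -5   -4   -5   -2   -5   -4   -4   12   -3   -3   -2   -3   -4   -7   -6   -3
Q   -2   -5   -1    3   -5   -4    1   -5    2   -4   -1    0   -3    9    1   -1   -1   -4   -4   -3   -2
R   -3   -6   -3   -1   -5   -4    0   -5    3   -4   -3   -1   -3    1    9   -2   -2   -4   -5   -4   -2
S    2   -2   -1   -1   -4   -1   -2   -4   -1   -4   -3    1   -2   -1   -2    7    2   -3   -6   -3   -1
T    0   -2   -2   -2   -4   -3   -3   -2   -1   -3   -1    0   -3   -1   -2    2    8    0   -5   -3   -1
V   -1   -2   -6   -4   -2   -6   -5    4   -4    1    1   -5   -4   -4   -4   -3    0    7   -5   -3   -2
W   -5   -5   -8   -6    0   -6   -4   -5   -6   -4   -3   -7   -7   -4   -5   -6   -5   -5   16    3   -5
Y   -4   -5   -6   -5    4   -6    3   -3   -4   -2   -3   -4   -6   -3   -4   -3   -3   -3    3   11   -3
X   -1   -4   -3   -2   -3   -3   -2   -2   -2   -2   -2   -2   -3   -2   -2   -1   -1   -2   -5   -3   -2
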