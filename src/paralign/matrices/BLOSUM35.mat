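# BLOSUM35 substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    5   -2   -1   -1   -2    0   -2   -1    0   -2    0   -1   -2    0   -1    1    0    0   -2   -1    0
C   -2   15   -3   -1   -4   -3   -4   -4   -2   -2   -4   -1   -4   -3   -3   -3   -1   -2   -5   -5   -2
D   -1   -3    8    2   -3   -2    0   -3   -1   -2   -3    1   -1   -1   -1   -1   -1   -2   -3   -2   -1
E   -1   -1    2    6   -3   -2   -1   -3    1   -1   -2   -1    0    2   -1    0   -1   -2   -1   -1   -1
F   -2   -4   -3   -3    8   -3   -3    1   -1    2    0   -1   -4   -4   -1   -1   -1    1    1    3   -1
G    0   -3   -2   -2   -3    7   -2   -3   -1   -3   -1    1   -2   -2   -2    1   -2   -3   -1   -2   -1
H   -2   -4    0   -1   -3   -2   12   -3   -2   -2    1    1   -1   -1   -1   -1   -2   -4   -4    0   -1
I   -1   -4   -3   -3    1   -3   -3    5   -2    2    1   -1   -1   -2   -3   -2   -1    4   -1    0    0
K    0   -2   -1    1   -1   -1   -2   -2    5   -2    0    0    0    0    2    0    0   -2    0   -1    0
L   -2   -2   -2   -1    2   -3   -2    2   -2    5    3   -2   -3   -2   -2   -2    0    2    0    0    0
M    0   -4   -3   -2    0   -1    1    1    0    3    6   -1   -3   -1    0   -1    0    1    1    0    0
N   -1   -1    1   -1   -1    1    1   -1    0   -2   -1    7   -2    1   -1    0    0   -2   -2   -2    0
P   -2   -4   -1    0   -4   -2   -1   -1    0   -3   -3   -2   10    0   -2   -2    0   -3   -4   -3   -1
Q    0   -3   -1    2   -4   -2   -1   -2    0   -2   -1    1    0    7    2    0    0   -3   -1    0   -1
R   -1   -3   -1   -1   -1   -2   -1   -3    2   -2    0   -1   -2    2    8   -1   -2   -1    0    0   -1
S    1   -3   -1    0   -1    1   -1   -2    0   -2   -1    0   -2    0   -1    4    2   -1   -2   -1    0
T    0   -1   -1   -1   -1   -2   -2   -1    0    0    0    0    0    0   -2    2    5    1   -2   -2    0
V    0   -2   -2   -2    1   -3   -4    4   -2    2    1   -2   -3   -3   -1   -1    1    5   -2    0    0
W   -2   -5   -3   -1    1   -1   -4   -1    0    0    1   -2   -4   -1    0   -2   -2   -2   16    3   -1
Y   -1   -5   -2   -1    3   -2    0    0   -1    0    0   -2   -3    0    0   -1   -2    0    3    8   -1
X    0   -2   -1   -1   -1   -1   -1    0    0    0    0    0   -1   -1   -1    0    0    0   -1   -1   -1
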