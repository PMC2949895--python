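# PAM110 substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    3   -3   -1    0   -4    1   -3   -1   -3   -3   -2   -1    1   -1   -3    1    1    0   -7   -4   -1
C   -3    9   -7   -7   -6   -5   -4   -3   -7   -8   -7   -5   -4   -7   -4   -1   -3   -3   -9   -1   -4
D   -1   -7    5    4   -7    0    0   -3   -1   -6   -5    2   -3    1   -4   -1   -1   -4   -8   -5   -2
E    0   -7    4    5   -7   -1   -1   -3   -1   -5   -3    1   -2    2   -3   -1   -2   -3   -9   -5   -2
F   -4   -6   -7   -7    8   -5   -3    0   -7    0   -1   -4   -6   -6   -5   -4   -4   -3   -1    4   -4
G    1   -5    0   -1   -5    5   -4   -4   -3   -6   -4    0   -2   -3   -4    0   -2   -2   -8   -7   -2
H   -3   -4    0   -1   -3   -4    7   -4   -2   -3   -4    2   -1    3    1   -2   -3   -3   -4   -1   -2
I   -1   -3   -3   -3    0   -4   -4    6   -3    1    1   -2   -4   -3   -3   -3    0    3   -7   -2   -2
K   -3   -7   -1   -1   -7   -3   -2   -3    5   -4    0    1   -3    0    2   -1   -1   -4   -5   -5   -2
L   -3   -8   -6   -5    0   -6   -3    1   -4    6    3   -4   -4   -2   -4   -4   -3    1   -3   -3   -2
M   -2   -7   -5   -3   -1   -4   -4    1    0    3    8   -3   -4   -1   -1   -2   -1    1   -6   -5   -2
N   -1   -5    2    1   -4    0    2   -2    1   -4   -3    4   -2    0   -1    1    0   -3   -5   -2   -1
P    1   -4   -3   -2   -6   -2   -1   -4   -3   -4   -4   -2    6    0   -1    0   -1   -2   -7   -7   -2
Q   -1   -7    1    2   -6   -3    3   -3    0   -2   -1    0    0    6    1   -2   -2   -3   -6   -6   -1
R   -3   -4   -4   -3   -5   -4    1   -3    2   -4   -1   -1   -1    1    7   -1   -2   -4    1   -5   -2
S    1   -1   -1   -1   -4    0   -2   -3   -1   -4   -2    1    0   -2   -1    3    2   -2   -3   -3   -1
T    1   -3   -1   -2   -4   -2   -3    0   -1   -3   -1    0   -1   -2   -2    2    5    0   -6   -3   -1
V    0   -3   -4   -3   -3   -2   -3    3   -4    1    1   -3   -2   -3   -4   -2    0    5   -8   -4   -2
W   -7   -9   -8   -9   -1   -8   -4   -7   -5   -3   -6   -5   -7   -6    1   -3   -6   -8   12   -2   -5
Y   -4   -1   -5   -5    4   -7   -1   -2   -5   -3   -5   -2   -7   -6   -5   -3   -3   -4   -2    8   -3
X   -1   -4   -2   -2   -4   -2   -2   -2   -2   -2   -2   -1   -2   -1   -2   -1   -1   -2   -5   -3   -2
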