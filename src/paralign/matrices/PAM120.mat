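# PAM120 substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    3   -3    0    0   -4    1   -3   -1   -2   -3   -2   -1    1   -1   -3    1    1    0   -7   -4   -1
C   -3    9   -7   -7   -6   -4   -4   -3   -7   -7   -6   -5   -4   -7   -4    0   -3   -3   -8   -1   -4
D    0   -7    5    3   -7    0    0   -3   -1   -5   -4    2   -3    1   -3    0   -1   -3   -8   -5   -2
E    0   -7    3    5   -7   -1   -1   -3   -1   -4   -3    1   -2    2   -3   -1   -2   -3   -8   -5   -1
F   -4   -6   -7   -7    8   -5   -3    0   -7    0   -1   -4   -5   -6   -5   -3   -4   -3   -1    4   -3
G    1   -4    0   -1   -5    5   -4   -4   -3   -5   -4    0   -2   -3   -4    1   -1   -2   -8   -6   -2
H   -3   -4    0   -1   -3   -4    7   -4   -2   -3   -4    2   -1    3    1   -2   -3   -3   -3   -1   -2
I   -1   -3   -3   -3    0   -4   -4    6   -3    1    1   -2   -3   -3   -2   -2    0    3   -6   -2   -1
K   -2   -7   -1   -1   -7   -3   -2   -3    5   -4    0    1   -2    0    2   -1   -1   -4   -5   -5   -2
L   -3   -7   -5   -4    0   -5   -3    1   -4    5    3   -4   -3   -2   -4   -4   -3    1   -3   -2   -2
M   -2   -6   -4   -3   -1   -4   -4    1    0    3    8   -3   -3   -1   -1   -2   -1    1   -6   -4   -2
N   -1   -5    2    1   -4    0    2   -2    1   -4   -3    4   -2    0   -1    1    0   -3   -4   -2   -1
P    1   -4   -3   -2   -5   -2   -1   -3   -2   -3   -3   -2    6    0   -1    1   -1   -2   -7   -6   -2
Q   -1   -7    1    2   -6   -3    3   -3    0   -2   -1    0    0    6    1   -2   -2   -3   -6   -5   -1
R   -3   -4   -3   -3   -5   -4    1   -2    2   -4   -1   -1   -1    1    6   -1   -2   -3    1   -5   -2
S    1    0    0   -1   -3    1   -2   -2   -1   -4   -2    1    1   -2   -1    3    2   -2   -2   -3   -1
T    1   -3   -1   -2   -4   -1   -3    0   -1   -3   -1    0   -1   -2   -2    2    4    0   -6   -3   -1
V    0   -3   -3   -3   -3   -2   -3    3   -4    1    1   -3   -2   -3   -3   -2    0    5   -8   -3   -1
W   -7   -8   -8   -8   -1   -8   -3   -6   -5   -3   -6   -4   -7   -6    1   -2   -6   -8   12   -2   -5
Y   -4   -1   -5   -5    4   -6   -1   -2   -5   -2   -4   -2   -6   -5   -5   -3   -3   -3   -2    8   -3
X   -1   -4   -2   -1   -3   -2   -2   -1   -2   -2   -2   -1   -2   -1   -2   -1   -1   -1   -5   -3   -2
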