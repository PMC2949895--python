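# PAM90 substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    4   -3   -1    0   -5    0   -4   -2   -3   -3   -2   -1    0   -2   -4    1    1    0   -8   -5   -1
C   -3    9   -8   -8   -7   -5   -5   -3   -8   -9   -8   -6   -5   -8   -5   -1   -4   -3  -10   -1   -5
D   -1   -8    6    4   -8   -1   -1   -4   -2   -7   -5    3   -4    0   -5   -1   -2   -4   -9   -6   -2
E    0   -8    4    6   -8   -1   -1   -3   -2   -5   -4    0   -2    2   -4   -2   -2   -3  -10   -6   -2
F   -5   -7   -8   -8    8   -6   -3    0   -8    0   -1   -5   -6   -7   -6   -4   -5   -4   -2    4   -4
G    0   -5   -1   -1   -6    5   -5   -5   -4   -6   -5   -1   -3   -3   -5    0   -2   -3   -9   -8   -2
H   -4   -5   -1   -1   -3   -5    8   -5   -2   -3   -5    2   -2    2    1   -3   -3   -4   -4   -1   -2
I   -2   -3   -4   -3    0   -5   -5    6   -3    1    1   -3   -4   -4   -3   -3    0    3   -8   -3   -2
K   -3   -8   -2   -2   -8   -4   -2   -3    5   -5    0    1   -3   -1    2   -1   -1   -5   -6   -6   -2
L   -3   -9   -7   -5    0   -6   -3    1   -5    6    2   -4   -4   -3   -5   -5   -3    0   -3   -3   -3
M   -2   -8   -5   -4   -1   -5   -5    1    0    2    9   -4   -4   -2   -2   -3   -2    1   -7   -6   -2
N   -1   -6    3    0   -5   -1    2   -3    1   -4   -4    5   -2   -1   -2    1    0   -4   -5   -2   -1
P    0   -5   -4   -2   -6   -3   -2   -4   -3   -4   -4   -2    7   -1   -1    0   -1   -3   -8   -8   -2
Q   -2   -8    0    2   -7   -3    2   -4   -1   -3   -2   -1   -1    6    0   -2   -3   -4   -7   -6   -2
R   -4   -5   -5   -4   -6   -5    1   -3    2   -5   -2   -2   -1    0    7   -1   -3   -4    0   -6   -2
S    1   -1   -1   -2   -4    0   -3   -3   -1   -5   -3    1    0   -2   -1    4    2   -3   -3   -4   -1
T    1   -4   -2   -2   -5   -2   -3    0   -1   -3   -2    0   -1   -3   -3    2    5   -1   -7   -4   -1
V    0   -3   -4   -3   -4   -3   -4    3   -5    0    1   -4   -3   -4   -4   -3   -1    6   -9   -4   -2
W   -8  -10   -9  -10   -2   -9   -4   -8   -6   -3   -7   -5   -8   -7    0   -3   -7   -9   13   -2   -6
Y   -5   -1   -6   -6    4   -8   -1   -3   -6   -3   -6   -2   -8   -6   -6   -4   -4   -4   -2    9   -4
X   -1   -5   -2   -2   -4   -2   -2   -2   -2   -3   -2   -1   -2   -2   -2   -1   -1   -2   -6   -4   -2
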