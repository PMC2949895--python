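# PAM160 substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    2   -2    0    0   -3    1   -2   -1   -2   -2   -1    0    1   -1   -2    1    1    0   -5   -3    0
C   -2    9   -5   -5   -5   -3   -3   -2   -5   -6   -5   -4   -3   -5   -3    0   -2   -2   -7    0   -3
D    0   -5    4    3   -6    0    0   -3    0   -4   -3    2   -2    1   -2    0   -1   -3   -6   -4   -1
E    0   -5    3    4   -5    0    0   -2   -1   -3   -2    1   -1    2   -2    0   -1   -2   -7   -4   -1
F   -3   -5   -6   -5    7   -4   -2    0   -5    1    0   -3   -4   -5   -4   -3   -3   -2   -1    5   -3
G    1   -3    0    0   -4    4   -3   -3   -2   -4   -3    0   -1   -2   -3    1   -1   -2   -7   -5   -1
H   -2   -3    0    0   -2   -3    6   -3   -1   -2   -3    2   -1    2    1   -1   -2   -2   -3    0   -1
I   -1   -2   -3   -2    0   -3   -3    5   -2    2    2   -2   -2   -2   -2   -2    0    3   -5   -2   -1
K   -2   -5    0   -1   -5   -2   -1   -2    4   -3    0    1   -2    0    3   -1    0   -3   -4   -4   -1
L   -2   -6   -4   -3    1   -4   -2    2   -3    5    3   -3   -3   -2   -3   -3   -2    1   -2   -2   -2
M   -1   -5   -3   -2    0   -3   -3    2    0    3    7   -2   -2   -1   -1   -2   -1    1   -4   -3   -1
N    0   -4    2    1   -3    0    2   -2    1   -3   -2    3   -1    0   -1    1    0   -2   -4   -2    0
P    1   -3   -2   -1   -4   -1   -1   -2   -2   -3   -2   -1    5    0   -1    1    0   -2   -5   -5   -1
Q   -1   -5    1    2   -5   -2    2   -2    0   -2   -1    0    0    5    1   -1   -1   -2   -5   -4   -1
R   -2   -3   -2   -2   -4   -3    1   -2    3   -3   -1   -1   -1    1    6   -1   -1   -3    1   -4   -1
S    1    0    0    0   -3    1   -1   -2   -1   -3   -2    1    1   -1   -1    2    1   -1   -2   -3    0
T    1   -2   -1   -1   -3   -1   -2    0    0   -2   -1    0    0   -1   -1    1    3    0   -5   -3    0
V    0   -2   -3   -2   -2   -2   -2    3   -3    1    1   -2   -2   -2   -3   -1    0    4   -6   -3   -1
W   -5   -7   -6   -7   -1   -7   -3   -5   -4   -2   -4   -4   -5   -5    1   -2   -5   -6   12   -1   -4
Y   -3    0   -4   -4    5   -5    0   -2   -4   -2   -3   -2   -5   -4   -4   -3   -3   -3   -1    8   -3
X    0   -3   -1   -1   -3   -1   -1   -1   -1   -2   -1    0   -1   -1   -1    0    0   -1   -4   -3   -1
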