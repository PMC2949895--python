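# DAYHOFF substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    2   -2    0    0   -4    1   -1   -1   -1   -2   -1    0    1    0   -2    1    1    0   -6   -3    0
C   -2   12   -5   -5   -4   -3   -3   -2   -5   -6   -5   -4   -3   -5   -4    0   -2   -2   -8    0   -3
D    0   -5    4    3   -6    1    1   -2    0   -4   -3    2   -1    2   -1    0    0   -2   -7   -4   -1
E    0   -5    3    4   -5    0    1   -2    0   -3   -2    1   -1    2   -1    0    0   -2   -7   -4   -1
F   -4   -4   -6   -5    9   -5   -2    1   -5    2    0   -4   -5   -5   -4   -3   -3   -1    0    7   -2
G    1   -3    1    0   -5    5   -2   -3   -2   -4   -3    0   -1   -1   -3    1    0   -1   -7   -5   -1
H   -1   -3    1    1   -2   -2    6   -2    0   -2   -2    2    0    3    2   -1   -1   -2   -3    0   -1
I   -1   -2   -2   -2    1   -3   -2    5   -2    2    2   -2   -2   -2   -2   -1    0    4   -5   -1   -1
K   -1   -5    0    0   -5   -2    0   -2    5   -3    0    1   -1    1    3    0    0   -2   -3   -4   -1
L   -2   -6   -4   -3    2   -4   -2    2   -3    6    4   -3   -3   -2   -3   -3   -2    2   -2   -1   -1
M   -1   -5   -3   -2    0   -3   -2    2    0    4    6   -2   -2   -1    0   -2   -1    2   -4   -2   -1
N    0   -4    2    1   -4    0    2   -2    1   -3   -2    2   -1    1    0    1    0   -2   -4   -2    0
P    1   -3   -1   -1   -5   -1    0   -2   -1   -3   -2   -1    6    0    0    1    0   -1   -6   -5   -1
Q    0   -5    2    2   -5   -1    3   -2    1   -2   -1    1    0    4    1   -1   -1   -2   -5   -4   -1
R   -2   -4   -1   -1   -4   -3    2   -2    3   -3    0    0    0    1    6    0   -1   -2    2   -4   -1
S    1    0    0    0   -3    1   -1   -1    0   -3   -2    1    1   -1    0    2    1   -1   -2   -3    0
T    1   -2    0    0   -3    0   -1    0    0   -2   -1    0    0   -1   -1    1    3    0   -5   -3    0
V    0   -2   -2   -2   -1   -1   -2    4   -2    2    2   -2   -1   -2   -2   -1    0    4   -6   -2   -1
W   -6   -8   -7   -7    0   -7   -3   -5   -3   -2   -4   -4   -6   -5    2   -2   -5   -6   17    0   -4
Y   -3    0   -4   -4    7   -5    0   -1   -4   -1   -2   -2   -5   -4   -4   -3   -3   -2    0   10   -2
X    0   -3   -1   -1   -2   -1   -1   -1   -1   -1   -1    0   -1   -1   -1    0    0   -1   -4   -2   -1
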