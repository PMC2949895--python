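# GONNET250 substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    2    0    0    0   -2    0   -1   -1    0   -1   -1    0    0    0   -1    1    1    0   -4   -2    0
C    0   12   -3   -3   -1   -2   -1   -1   -3   -2   -1   -2   -3   -2   -2    0    0    0   -1    0   -3
D    0   -3    5    3   -4    0    0   -4    0   -4   -3    2   -1    1    0    0    0   -3   -5   -3   -1
E    0   -3    3    4   -4   -1    0   -3    1   -3   -2    1    0    2    0    0    0   -2   -4   -3   -1
F   -2   -1   -4   -4    7   -5    0    1   -3    2    2   -3   -4   -3   -3   -3   -2    0    4    5   -2
G    0   -2    0   -1   -5    7   -1   -4   -1   -4   -4    0   -2   -1   -1    0   -1   -3   -4   -4   -1
H   -1   -1    0    0    0   -1    6   -2    1   -2   -1    1   -1    1    1    0    0   -2   -1    2   -1
I   -1   -1   -4   -3    1   -4   -2    4   -2    3    2   -3   -3   -2   -2   -2   -1    3   -2   -1   -1
K    0   -3    0    1   -3   -1    1   -2    3   -2   -1    1   -1    2    3    0    0   -2   -4   -2   -1
L   -1   -2   -4   -3    2   -4   -2    3   -2    4    3   -3   -2   -2   -2   -2   -1    2   -1    0   -1
M   -1   -1   -3   -2    2   -4   -1    2   -1    3    4   -2   -2   -1   -2   -1   -1    2   -1    0   -1
N    0   -2    2    1   -3    0    1   -3    1   -3   -2    4   -1    1    0    1    0   -2   -4   -1    0
P    0   -3   -1    0   -4   -2   -1   -3   -1   -2   -2   -1    8    0   -1    0    0   -2   -5   -3   -1
Q    0   -2    1    2   -3   -1    1   -2    2   -2   -1    1    0    3    2    0    0   -2   -3   -2   -1
R   -1   -2    0    0   -3   -1    1   -2    3   -2   -2    0   -1    2    5    0    0   -2   -2   -2   -1
S    1    0    0    0   -3    0    0   -2    0   -2   -1    1    0    0    0    2    2   -1   -3   -2    0
T    1    0    0    0   -2   -1    0   -1    0   -1   -1    0    0    0    0    2    2    0   -4   -2    0
V    0    0   -3   -2    0   -3   -2    3   -2    2    2   -2   -2   -2   -2   -1    0    3   -3   -1   -1
W   -4   -1   -5   -4    4   -4   -1   -2   -4   -1   -1   -4   -5   -3   -2   -3   -4   -3   14    4   -4
Y   -2    0   -3   -3    5   -4    2   -1   -2    0    0   -1   -3   -2   -2   -2   -2   -1    4    8   -2
X    0   -3   -1   -1   -2   -1   -1   -1   -1   -1   -1    0   -1   -1   -1    0    0   -1   -4   -2   -1
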