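# BLOSUM30 substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    4   -3    0    0   -2    0   -2    0    0   -1    1    0   -1    1   -1    1    1    1   -5   -4    0
C   -3   17   -3    1   -3   -4   -5   -2   -3    0   -2   -1   -3   -2   -2   -2   -2   -2   -2   -6   -2
D    0   -3    9    1   -5   -1   -2   -4    0   -1   -3    1   -1   -1   -1    0   -1   -2   -4   -1   -1
E    0    1    1    6   -4   -2    0   -3    2   -1   -1   -1    1    2   -1    0   -2   -3   -1   -2   -1
F   -2   -3   -5   -4   10   -3   -3    0   -1    2   -2   -1   -4   -3   -1   -1   -2    1    1    3   -1
G    0   -4   -1   -2   -3    8   -3   -1   -1   -2   -2    0   -1   -2   -2    0   -2   -3    1   -3   -1
H   -2   -5   -2    0   -3   -3   14   -2   -2   -1    2   -1    1    0   -1   -1   -2   -3   -5    0   -1
I    0   -2   -4   -3    0   -1   -2    6   -2    2    1    0   -3   -2   -3   -1    0    4   -3   -1    0
K    0   -3    0    2   -1   -1   -2   -2    4   -2    2    0    1    0    1    0   -1   -2   -2   -1    0
L   -1    0   -1   -1    2   -2   -1    2   -2    4    2   -2   -3   -2   -2   -2    0    1   -2    3    0
M    1   -2   -3   -1   -2   -2    2    1    2    2    6    0   -4   -1    0   -2    0    0   -3   -1    0
N    0   -1    1   -1   -1    0   -1    0    0   -2    0    8   -3   -1   -2    0    1   -2   -7   -4    0
P   -1   -3   -1    1   -4   -1    1   -3    1   -3   -4   -3   11    0   -1   -1    0   -4   -3   -2   -1
Q    1   -2   -1    2   -3   -2    0   -2    0   -2   -1   -1    0    8    3   -1    0   -3   -1   -1    0
R   -1   -2   -1   -1   -1   -2   -1   -3    1   -2    0   -2   -1    3    8   -1   -3   -1    0    0   -1
S    1   -2    0    0   -1    0   -1   -1    0   -2   -2    0   -1   -1   -1    4    2   -1   -3   -2    0
T    1   -2   -1   -2   -2   -2   -2    0   -1    0    0    1    0    0   -3    2    5    1   -5   -1    0
V    1   -2   -2   -3    1   -3   -3    4   -2    1    0   -2   -4   -3   -1   -1    1    5   -3    1    0
W   -5   -2   -4   -1    1    1   -5   -3   -2   -2   -3   -7   -3   -1    0   -3   -5   -3   20    5   -2
Y   -4   -6   -1   -2    3   -3    0   -1   -1    3   -1   -4   -2   -1    0   -2   -1    1    5    9   -1
X    0   -2   -1   -1   -1   -1   -1    0    0    0    0    0   -1    0   -1    0    0    0   -2   -1   -1
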