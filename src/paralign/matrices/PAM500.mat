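# PAM500 substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    1   -2    1    1   -3    1    0    0    0   -1   -1    0    1    0   -1    1    1    0   -6   -3    0
C   -2   22   -5   -5   -3   -3   -4   -2   -5   -6   -5   -3   -2   -5   -4    0   -2   -2   -9    2   -2
D    1   -5    3    3   -5    1    1   -2    1   -3   -2    2    0    2    0    1    0   -1   -7   -5    0
E    1   -5    3    3   -5    1    1   -2    1   -3   -1    1    0    2    0    1    0   -1   -7   -5    0
F   -3   -3   -5   -5   13   -5   -2    2   -5    4    1   -4   -4   -4   -4   -3   -3    0    3   13   -2
G    1   -3    1    1   -5    4   -1   -2    0   -3   -2    1    1    0   -1    1    1   -1   -8   -5    0
H    0   -4    1    1   -2   -1    4   -2    1   -2   -1    1    0    2    2    0    0   -2   -2    0    0
I    0   -2   -2   -2    2   -2   -2    3   -2    4    3   -1   -1   -1   -2   -1    0    3   -5    0    0
K    0   -5    1    1   -5    0    1   -2    4   -2    0    1    0    1    4    0    0   -2   -3   -5    0
L   -1   -6   -3   -3    4   -3   -2    4   -2    7    4   -2   -2   -2   -2   -2   -1    3   -1    1   -1
M   -1   -5   -2   -1    1   -2   -1    3    0    4    4   -1   -1   -1    0   -1    0    2   -4   -1    0
N    0   -3    2    1   -4    1    1   -1    1   -2   -1    1    0    1    1    1    0   -1   -5   -3    0
P    1   -2    0    0   -4    1    0   -1    0   -2   -1    0    4    1    0    1    1   -1   -6   -5    0
Q    0   -5    2    2   -4    0    2   -1    1   -2   -1    1    1    2    2    0    0   -1   -5   -4    0
R   -1   -4    0    0   -4   -1    2   -2    4   -2    0    1    0    2    5    0    0   -2    4   -4    0
S    1    0    1    1   -3    1    0   -1    0   -2   -1    1    1    0    0    1    1   -1   -3   -3    0
T    1   -2    0    0   -3    1    0    0    0   -1    0    0    1    0    0    1    1    0   -6   -3    0
V    0   -2   -1   -1    0   -1   -2    3   -2    3    2   -1   -1   -1   -2   -1    0    3   -6   -1    0
W   -6   -9   -7   -7    3   -8   -2   -5   -3   -1   -4   -5   -6   -5    4   -3   -6   -6   34    2   -4
Y   -3    2   -5   -5   13   -5    0    0   -5    1   -1   -3   -5   -4   -4   -3   -3   -1    2   15   -2
X    0   -2    0    0   -2    0    0    0    0   -1    0    0    0    0    0    0    0    0   -4   -2    0
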