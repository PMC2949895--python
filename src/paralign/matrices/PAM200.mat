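# PAM200 substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    3   -3    0    0   -4    1   -2   -1   -2   -2   -2    0    1   -1   -2    1    1    0   -7   -4    0
C   -3   12   -6   -7   -6   -4   -4   -3   -7   -7   -6   -5   -4   -7   -4    0   -3   -2   -9    0   -4
D    0   -6    5    4   -7    0    0   -3    0   -5   -4    3   -2    2   -2    0    0   -3   -8   -5   -1
E    0   -7    4    5   -7    0    0   -3    0   -4   -3    2   -1    3   -2    0   -1   -2   -9   -5   -1
F   -4   -6   -7   -7   10   -6   -2    1   -7    2    0   -4   -6   -6   -5   -4   -4   -2    0    7   -3
G    1   -4    0    0   -6    6   -3   -3   -2   -5   -4    0   -1   -2   -4    1    0   -2   -8   -6   -1
H   -2   -4    0    0   -2   -3    8   -3   -1   -3   -3    2   -1    3    2   -1   -2   -3   -3    0   -1
I   -1   -3   -3   -3    1   -3   -3    6   -2    2    2   -2   -3   -3   -2   -2    0    4   -6   -2   -1
K   -2   -7    0    0   -7   -2   -1   -2    6   -4    1    1   -2    1    4    0    0   -3   -4   -5   -1
L   -2   -7   -5   -4    2   -5   -3    2   -4    7    4   -4   -3   -2   -4   -4   -2    2   -2   -2   -2
M   -2   -6   -4   -3    0   -4   -3    2    1    4    8   -2   -3   -1   -1   -2   -1    2   -5   -3   -1
N    0   -5    3    2   -4    0    2   -2    1   -4   -2    3   -1    1    0    1    0   -2   -5   -2    0
P    1   -4   -2   -1   -6   -1   -1   -3   -2   -3   -3   -1    7    0    0    1    0   -2   -7   -6   -1
Q   -1   -7    2    3   -6   -2    3   -3    1   -2   -1    1    0    5    1   -1   -1   -3   -6   -5   -1
R   -2   -4   -2   -2   -5   -4    2   -2    4   -4   -1    0    0    1    7   -1   -1   -3    2   -5   -1
S    1    0    0    0   -4    1   -1   -2    0   -4   -2    1    1   -1   -1    2    2   -1   -3   -3    0
T    1   -3    0   -1   -4    0   -2    0    0   -2   -1    0    0   -1   -1    2    4    0   -6   -3    0
V    0   -2   -3   -2   -2   -2   -3    4   -3    2    2   -2   -2   -3   -3   -1    0    5   -8   -3   -1
W   -7   -9   -8   -9    0   -8   -3   -6   -4   -2   -5   -5   -7   -6    2   -3   -6   -8   18   -1   -5
Y   -4    0   -5   -5    7   -6    0   -2   -5   -2   -3   -2   -6   -5   -5   -3   -3   -3   -1   11   -3
X    0   -4   -1   -1   -3   -1   -1   -1   -1   -2   -1    0   -1   -1   -1    0    0   -1   -5   -3   -1
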