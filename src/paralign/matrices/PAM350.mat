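# PAM350 substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    2   -2    1    1   -4    2   -1    0   -1   -2   -1    0    1    0   -1    1    1    0   -7   -4    0
C   -2   18   -6   -6   -5   -4   -4   -3   -6   -7   -6   -4   -3   -6   -4    0   -2   -2  -10    1   -3
D    1   -6    4    4   -6    1    1   -2    1   -4   -3    2    0    2   -1    1    0   -2   -8   -5   -1
E    1   -6    4    4   -6    1    1   -2    0   -4   -2    2    0    3    0    0    0   -2   -8   -5    0
F   -4   -5   -6   -6   13   -6   -2    2   -6    3    1   -4   -5   -5   -5   -4   -3   -1    1   11   -2
G    2   -4    1    1   -6    5   -2   -2   -1   -4   -3    1    0   -1   -2    1    1   -1   -8   -6   -1
H   -1   -4    1    1   -2   -2    7   -2    1   -2   -2    2    0    3    2   -1   -1   -2   -3    0    0
I    0   -3   -2   -2    2   -2   -2    5   -2    4    3   -2   -2   -2   -2   -1    0    4   -6    0    0
K   -1   -6    1    0   -6   -1    1   -2    5   -3    0    1   -1    1    4    0    0   -2   -4   -5   -1
L   -2   -7   -4   -4    3   -4   -2    4   -3    8    5   -3   -3   -2   -3   -3   -2    3   -2    0   -1
M   -1   -6   -3   -2    1   -3   -2    3    0    5    6   -2   -2   -1    0   -2   -1    2   -5   -2    0
N    0   -4    2    2   -4    1    2   -2    1   -3   -2    2    0    1    1    1    1   -2   -5   -3    0
P    1   -3    0    0   -5    0    0   -2   -1   -3   -2    0    6    1    0    1    1   -1   -7   -6    0
Q    0   -6    2    3   -5   -1    3   -2    1   -2   -1    1    1    4    2    0    0   -2   -5   -5    0
R   -1   -4   -1    0   -5   -2    2   -2    4   -3    0    1    0    2    7    0   -1   -3    4   -5   -1
S    1    0    1    0   -4    1   -1   -1    0   -3   -2    1    1    0    0    1    1   -1   -3   -3    0
T    1   -2    0    0   -3    1   -1    0    0   -2   -1    1    1    0   -1    1    2    0   -6   -3    0
V    0   -2   -2   -2   -1   -1   -2    4   -2    3    2   -2   -1   -2   -3   -1    0    5   -7   -2    0
W   -7  -10   -8   -8    1   -8   -3   -6   -4   -2   -5   -5   -7   -5    4   -3   -6   -7   27    1   -5
Y   -4    1   -5   -5   11   -6    0    0   -5    0   -2   -3   -6   -5   -5   -3   -3   -2    1   14   -2
X    0   -3   -1    0   -2   -1    0    0   -1   -1    0    0    0    0   -1    0    0    0   -5   -2   -1
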