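# PAM50 substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    5   -5   -2   -1   -7   -1   -5   -3   -5   -5   -4   -2    0   -3   -5    0    0   -1  -11   -6   -2
C   -5    9  -11  -11  -10   -7   -6   -5  -11  -12  -11   -8   -6  -11   -6   -2   -6   -5  -13   -3   -7
D   -2  -11    7    3  -12   -2   -2   -6   -3  -10   -8    2   -6   -1   -7   -2   -3   -6  -12   -9   -4
E   -1  -11    3    7  -11   -3   -3   -4   -3   -7   -5   -1   -4    2   -7   -3   -4   -5  -13   -7   -3
F   -7  -10  -12  -11    9   -8   -5   -1  -11   -1   -3   -7   -8  -10   -8   -5   -7   -6   -3    3   -6
G   -1   -7   -2   -3   -8    6   -7   -8   -6   -9   -7   -2   -4   -5   -7   -1   -4   -4  -12  -11   -4
H   -5   -6   -2   -3   -5   -7    9   -7   -4   -5   -8    1   -3    2    0   -4   -5   -5   -6   -2   -4
I   -3   -5   -6   -4   -1   -8   -7    8   -5    0    0   -4   -7   -6   -4   -5   -1    3  -11   -5   -3
K   -5  -11   -3   -3  -11   -6   -4   -5    6   -6   -1    0   -5   -2    1   -3   -2   -7   -9   -8   -4
L   -5  -12  -10   -7   -1   -9   -5    0   -6    6    2   -6   -6   -4   -7   -7   -5   -1   -5   -5   -5
M   -4  -11   -8   -5   -3   -7   -8    0   -1    2   10   -6   -6   -3   -3   -4   -3    0  -10   -8   -4
N   -2   -8    2   -1   -7   -2    1   -4    0   -6   -6    7   -4   -2   -4    1   -1   -6   -7   -3   -2
P    0   -6   -6   -4   -8   -4   -3   -7   -5   -6   -6   -4    8   -2   -3   -1   -3   -4  -11  -11   -4
Q   -3  -11   -1    2  -10   -5    2   -6   -2   -4   -3   -2   -2    8    0   -4   -4   -5  -10   -9   -3
R   -5   -6   -7   -7   -8   -7    0   -4    1   -7   -3   -4   -3    0    8   -2   -5   -6   -1   -8   -4
S    0   -2   -2   -3   -5   -1   -4   -5   -3   -7   -4    1   -1   -4   -2    6    1   -4   -4   -5   -2
T    0   -6   -3   -4   -7   -4   -5   -1   -2   -5   -3   -1   -3   -4   -5    1    6   -2  -10   -5   -2
V   -1   -5   -6   -5   -6   -4   -5    3   -7   -1    0   -6   -4   -5   -6   -4   -2    7  -12   -6   -3
W  -11  -13  -12  -13   -3  -12   -6  -11   -9   -5  -10   -7  -11  -10   -1   -4  -10  -12   13   -4   -9
Y   -6   -3   -9   -7    3  -11   -2   -5   -8   -5   -8   -3  -11   -9   -8   -5   -5   -6   -4    9   -6
X   -2   -7   -4   -3   -6   -4   -4   -3   -4   -5   -4   -2   -4   -3   -4   -2   -2   -3   -9   -6   -4
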