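# PAM30 substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    6   -6   -3   -2   -8   -2   -7   -5   -7   -6   -5   -4   -2   -4   -7    0   -1   -2  -13   -8   -3
C   -6   10  -14  -14  -13   -9   -7   -6  -14  -15  -13  -11   -8  -14   -8   -3   -8   -6  -15   -4   -9
D   -3  -14    8    2  -15   -3   -4   -7   -4  -12  -11    2   -8   -2  -10   -4   -5   -8  -15  -11   -5
E   -2  -14    2    8  -14   -4   -5   -5   -4   -9   -7   -2   -5    1   -9   -4   -6   -6  -17   -8   -5
F   -8  -13  -15  -14    9   -9   -6   -2  -14   -3   -4   -9  -10  -13   -9   -6   -9   -8   -4    2   -8
G   -2   -9   -3   -4   -9    6   -9  -11   -7  -10   -8   -3   -6   -7   -9   -2   -6   -5  -15  -14   -5
H   -7   -7   -4   -5   -6   -9    9   -9   -6   -6  -10    0   -4    1   -2   -6   -7   -6   -7   -3   -5
I   -5   -6   -7   -5   -2  -11   -9    8   -6   -1   -1   -5   -8   -8   -5   -7   -2    2  -14   -6   -5
K   -7  -14   -4   -4  -14   -7   -6   -6    7   -8   -2   -1   -6   -3    0   -4   -3   -9  -12   -9   -5
L   -6  -15  -12   -9   -3  -10   -6   -1   -8    7    1   -7   -7   -5   -8   -8   -7   -2   -6   -7   -6
M   -5  -13  -11   -7   -4   -8  -10   -1   -2    1   11   -9   -8   -4   -4   -5   -4   -1  -13  -11   -5
N   -4  -11    2   -2   -9   -3    0   -5   -1   -7   -9    8   -6   -3   -6    0   -2   -8   -8   -4   -3
P   -2   -8   -8   -5  -10   -6   -4   -8   -6   -7   -8   -6    8   -3   -4   -2   -4   -6  -14  -13   -5
Q   -4  -14   -2    1  -13   -7    1   -8   -3   -5   -4   -3   -3    8   -2   -5   -5   -7  -13  -12   -5
R   -7   -8  -10   -9   -9   -9   -2   -5    0   -8   -4   -6   -4   -2    8   -3   -6   -8   -2  -10   -6
S    0   -3   -4   -4   -6   -2   -6   -7   -4   -8   -5    0   -2   -5   -3    6    0   -6   -5   -7   -3
T   -1   -8   -5   -6   -9   -6   -7   -2   -3   -7   -4   -2   -4   -5   -6    0    7   -3  -13   -6   -4
V   -2   -6   -8   -6   -8   -5   -6    2   -9   -2   -1   -8   -6   -7   -8   -6   -3    7  -15   -7   -5
W  -13  -15  -15  -17   -4  -15   -7  -14  -12   -6  -13   -8  -14  -13   -2   -5  -13  -15   13   -5  -11
Y   -8   -4  -11   -8    2  -14   -3   -6   -9   -7  -11   -4  -13  -12  -10   -7   -6   -7   -5   10   -7
X   -3   -9   -5   -5   -8   -5   -5   -5   -5   -6   -5   -3   -5   -5   -6   -3   -4   -5  -11   -7   -5
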