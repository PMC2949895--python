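# PAM20 substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    6   -8   -4   -3   -9   -3   -8   -6   -8   -7   -6   -5   -2   -5   -8   -1   -1   -3  -16   -9   -4
C   -8   10  -16  -16  -15  -11   -8   -7  -16  -17  -16  -13   -9  -16   -9   -4   -9   -7  -18   -5  -11
D   -4  -16    8    2  -17   -4   -5   -9   -6  -15  -13    1   -9   -4  -12   -5   -6   -9  -17  -13   -7
E   -3  -16    2    8  -16   -5   -6   -6   -5  -10   -8   -3   -7    0  -11   -5   -7   -8  -19   -9   -6
F   -9  -15  -17  -16    9  -10   -7   -3  -16   -4   -5  -10  -11  -15  -10   -7  -10   -9   -6    1   -9
G   -3  -11   -4   -5  -10    7  -10  -13   -8  -12  -10   -4   -7   -8  -11   -3   -7   -7  -17  -16   -6
H   -8   -8   -5   -6   -7  -10    9  -11   -8   -7  -13   -1   -5    0   -3   -7   -8   -7   -8   -4   -6
I   -6   -7   -9   -6   -3  -13  -11    9   -7   -2   -2   -6  -10   -9   -6   -8   -3    1  -16   -7   -6
K   -8  -16   -6   -5  -16   -8   -8   -7    7   -9   -3   -2   -8   -4   -1   -5   -4  -10  -14  -10   -6
L   -7  -17  -15  -10   -4  -12   -7   -2   -9    7    0   -8   -8   -6  -10   -9   -8   -3   -7   -8   -7
M   -6  -16  -13   -8   -5  -10  -13   -2   -3    0   11  -11   -9   -5   -5   -6   -5   -2  -15  -13   -6
N   -5  -13    1   -3  -10   -4   -1   -6   -2   -8  -11    8   -7   -5   -7   -1   -3   -9   -9   -5   -4
P   -2   -9   -9   -7  -11   -7   -5  -10   -8   -8   -9   -7    8   -4   -5   -3   -5   -7  -16  -16   -6
Q   -5  -16   -4    0  -15   -8    0   -9   -4   -6   -5   -5   -4    9   -2   -6   -7   -8  -15  -14   -6
R   -8   -9  -12  -11  -10  -11   -3   -6   -1  -10   -5   -7   -5   -2    9   -4   -8   -9   -3  -11   -7
S   -1   -4   -5   -5   -7   -3   -7   -8   -5   -9   -6   -1   -3   -6   -4    7    0   -8   -6   -8   -4
T   -1   -9   -6   -7  -10   -7   -8   -3   -4   -8   -5   -3   -5   -7   -8    0    7   -4  -15   -7   -5
V   -3   -7   -9   -8   -9   -7   -7    1  -10   -3   -2   -9   -7   -8   -9   -8   -4    7  -18   -8   -6
W  -16  -18  -17  -19   -6  -17   -8  -16  -14   -7  -15   -9  -16  -15   -3   -6  -15  -18   13   -6  -13
Y   -9   -5  -13   -9    1  -16   -4   -7  -10   -8  -13   -5  -16  -14  -11   -8   -7   -8   -6   10   -9
X   -4  -11   -7   -6   -9   -6   -6   -6   -6   -7   -6   -4   -6   -6   -7   -4   -5   -6  -13   -9   -6
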