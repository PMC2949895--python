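# PAM10 substitution matrix (protein)
     A    C    D    E    F    G    H    I    K    L    M    N    P    Q    R    S    T    V    W    Y    X
A    7  -10   -6   -5  -12   -4  -11   -8  -10   -9   -8   -7   -4   -7  -10   -3   -3   -5  -20  -11   -6
C  -10   10  -21  -20  -19  -13  -10   -9  -20  -21  -20  -17  -11  -20  -11   -6  -11   -9  -22   -7  -13
D   -6  -21    8    0  -21   -6   -7  -11   -8  -19  -17   -1  -12   -6  -17   -7   -8  -11  -21  -17   -9
E   -5  -20    0    8  -20   -7   -9   -8   -7  -13  -10   -5   -9   -1  -15   -7   -9  -10  -23  -11   -8
F  -12  -19  -21  -20    9  -12   -9   -5  -20   -5   -7  -12  -13  -19  -12   -9  -12  -12   -7   -1  -12
G   -4  -13   -6   -7  -12    7  -13  -17  -10  -14  -12   -6  -10  -10  -13   -4  -10   -9  -21  -20   -8
H  -11  -10   -7   -9   -9  -13   10  -13  -10   -9  -17   -2   -7   -2   -4   -9  -11   -9  -10   -6   -8
I   -8   -9  -11   -8   -5  -17  -13    9   -9   -4   -3   -8  -12  -11   -8  -10   -5   -1  -20   -9   -8
K  -10  -20   -8   -7  -20  -10  -10   -9    7  -11   -4   -4  -10   -6   -2   -7   -6  -13  -18  -12   -8
L   -9  -21  -19  -13   -5  -14   -9   -4  -11    7   -2  -10  -10   -8  -12  -12  -10   -5   -9  -10   -9
M   -8  -20  -17  -10   -7  -12  -17   -3   -4   -2   12  -15  -11   -7   -7   -8   -7   -4  -19  -17   -9
N   -7  -17   -1   -5  -12   -6   -2   -8   -4  -10  -15    9   -9   -7   -9   -2   -5  -12  -11   -7   -6
P   -4  -11  -12   -9  -13  -10   -7  -12  -10  -10  -11   -9    8   -6   -7   -4   -7   -9  -20  -20   -8
Q   -7  -20   -6   -1  -19  -10   -2  -11   -6   -8   -7   -7   -6    9   -4   -8   -9  -10  -19  -18   -8
R  -10  -11  -17  -15  -12  -13   -4   -8   -2  -12   -7   -9   -7   -4    9   -6  -10  -11   -5  -14   -9
S   -3   -6   -7   -7   -9   -4   -9  -10   -7  -12   -8   -2   -4   -8   -6    7   -2  -10   -8  -10   -6
T   -3  -11   -8   -9  -12  -10  -11   -5   -6  -10   -7   -5   -7   -9  -10   -2    8   -6  -19   -9   -7
V   -5   -9  -11  -10  -12   -9   -9   -1  -13   -5   -4  -12   -9  -10  -11  -10   -6    8  -22  -10   -8
W  -20  -22  -21  -23   -7  -21  -10  -20  -18   -9  -19  -11  -20  -19   -5   -8  -19  -22   13   -8  -16
Y  -11   -7  -17  -11   -1  -20   -6   -9  -12  -10  -17   -7  -20  -18  -14  -10   -9  -10   -8   10  -11
X   -6  -13   -9   -8  -12   -8   -8   -8   -8   -9   -9   -6   -8   -8   -9   -6   -7   -8  -16  -11   -8
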