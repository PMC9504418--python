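genotype,Barisal,Gazipur,Ishwardi,overall_mean,pi,bi,s2di
BRRI35A x BRRI36R,26.20,27.17,27.23,26.87,-1.04,1.707,0.02
BRRI99A x BRRI36R,27.43,29.17,30.43,29.01,1.1,4.414,0.19
BRRI35A x BRRI49R,25.43,27.80,27.80,27.01,-0.9,3.988,0.19
BRRI99A x BRRI49R,27.90,28.57,28.90,28.46,0.55,1.516,0.01
IR79156A x BRRI49R,25.50,26.23,26.73,26.16,-1.75,1.825,0.03
BRRI35A x BRRI37R,25.13,27.13,27.13,26.47,-1.44,3.370,0.13
BRRI48A x BRRI38R,28.77,28.50,28.40,28.56,0.65,-0.567,0.00
BRRI99A x BRRI38R,30.17,30.17,30.33,30.22,2.31,0.196,0.01
IR79156A x BRRI38R,27.60,27.60,27.90,27.70,-0.21,0.354,0.03
IR79156A x R line7,26.87,28.20,28.20,27.76,-0.15,2.247,0.06
BRRI35A x BRRI45R,26.70,27.03,27.03,26.92,-0.99,0.562,0.00
BRRI99A x BRRI45R,28.20,28.93,28.93,28.69,0.78,1.236,0.02
IR79156A x BRRI45R,28.77,29.07,29.07,28.97,1.06,0.505,0.00
BRRI35A x BRRI52R,26.80,27.07,27.07,26.98,-0.93,0.449,0.00
BRRI99A x BRRI31R,28.30,28.40,28.33,28.34,0.43,0.090,0.00
IR79156A x BRRI31R,27.73,27.77,27.77,27.76,-0.15,0.056,0.00
H-2264,27.73,27.80,27.87,27.80,-0.11,0.191,0.00
H-386,28.17,28.53,28.50,28.40,0.49,0.578,0.01
BRRI hybrid dhan3,28.07,28.13,28.47,28.22,0.31,0.505,0.03
BRRI hybrid dhan5,30.03,30.03,30.17,30.08,2.17,0.157,0.01
TejGold,26.07,26.07,26.33,26.16,-1.75,0.314,0.03
JhonokRaj,28.73,28.73,29.00,28.82,0.91,0.314,0.03
Heera-2,27.83,28.07,28.13,28.01,0.1,0.472,0.00
Gold,27.90,27.90,28.10,27.97,0.06,0.236,0.01
Teea,26.13,26.80,26.93,26.62,-1.29,1.281,0.00
SL8H,27.83,27.83,27.83,27.83,-0.08,0.000,0.00
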