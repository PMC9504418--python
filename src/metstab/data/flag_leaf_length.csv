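genotype,Barisal,Gazipur,Ishwardi,overall_mean,pi,bi,s2di
BRRI35A x BRRI36R,29.43,30.60,30.43,30.16,0.32,2.656,0.20
BRRI99A x BRRI36R,32.00,31.33,31.33,31.56,1.72,-1.732,0.04
BRRI35A x BRRI49R,27.00,27.23,27.23,27.16,-2.68,0.606,0.01
BRRI99A x BRRI49R,30.83,30.50,30.50,30.61,0.77,-0.866,0.01
IR79156A x BRRI49R,28.13,28.13,28.13,28.13,-1.71,0.000,0.00
BRRI35A x BRRI37R,26.37,29.40,29.40,28.39,-1.45,7.881,0.92
BRRI48A x BRRI38R,30.30,30.30,30.30,30.30,0.46,0.000,0.00
BRRI99A x BRRI38R,30.80,30.80,30.80,30.80,0.96,0.000,0.00
IR79156A x BRRI38R,31.23,31.23,31.23,31.23,1.39,0.000,0.00
IR79156A x R line7,29.23,29.23,29.23,29.23,-0.61,0.000,0.00
BRRI35A x BRRI45R,29.33,30.00,30.00,29.78,-0.06,1.732,0.04
BRRI99A x BRRI45R,31.27,31.60,31.60,31.49,1.65,0.866,0.01
IR79156A x BRRI45R,31.40,31.13,31.13,31.22,1.38,-0.693,0.01
BRRI35A x BRRI52R,27.37,28.43,28.43,28.08,-1.76,2.771,0.11
BRRI99A x BRRI31R,32.37,32.33,32.37,32.36,2.52,-0.012,0.00
IR79156A x BRRI31R,31.43,31.43,31.60,31.49,1.65,0.374,0.01
H-2264,31.93,32.40,31.37,31.90,2.06,-1.109,0.43
H-386,29.47,29.67,30.13,29.76,-0.08,1.568,0.03
BRRI hybrid dhan3,28.53,28.60,30.03,29.06,-0.78,3.393,0.47
BRRI hybrid dhan5,31.07,31.07,31.33,31.16,1.32,0.599,0.02
TejGold,27.83,27.83,28.17,27.94,-1.9,0.749,0.03
JhonokRaj,27.77,27.77,28.67,28.07,-1.77,2.022,0.20
Heera-2,28.47,28.80,28.87,28.71,-1.13,1.015,0.01
Gold,30.50,30.50,31.03,30.68,0.84,1.198,0.07
Teea,29.10,29.27,29.67,29.34,-0.5,1.331,0.02
SL8H,27.07,27.07,27.80,27.31,-2.53,1.647,0.13
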