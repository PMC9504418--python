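genotype,Barisal,Gazipur,Ishwardi,overall_mean,pi,bi,s2di
BRRI35A x BRRI36R,27.10,26.73,26.57,26.80,0.03,-1.706,0.00
BRRI99A x BRRI36R,28.03,28.30,28.57,28.30,1.53,1.611,0.01
BRRI35A x BRRI49R,25.47,28.13,28.13,27.24,0.47,9.297,0.32
BRRI99A x BRRI49R,26.47,26.47,27.97,26.97,0.2,3.837,0.75
IR79156A x BRRI49R,23.40,24.30,24.80,24.17,-2.6,4.416,0.01
BRRI35A x BRRI37R,24.60,26.10,26.17,25.62,-1.15,5.400,0.08
BRRI48A x BRRI38R,25.57,25.57,25.57,25.57,-1.2,-0.001,0.00
BRRI99A x BRRI38R,26.63,27.47,27.47,27.19,0.42,2.904,0.03
IR79156A x BRRI38R,26.70,27.23,27.23,27.06,0.29,1.858,0.01
IR79156A x R line7,25.30,25.30,25.53,25.38,-1.39,0.596,0.02
BRRI35A x BRRI45R,25.70,25.93,25.93,25.86,-0.91,0.812,0.00
BRRI99A x BRRI45R,27.77,27.83,27.83,27.81,1.04,0.231,0.00
IR79156A x BRRI45R,28.77,26.40,26.40,27.02,0.25,-6.510,0.16
BRRI35A x BRRI52R,26.33,26.53,26.17,26.34,-0.43,-0.242,0.06
BRRI99A x BRRI31R,28.40,28.50,28.50,28.47,1.7,0.348,0.00
IR79156A x BRRI31R,26.37,26.37,26.37,26.37,-0.4,-0.001,0.00
H-2264,27.37,26.67,26.67,26.90,0.13,-2.442,0.02
H-386,26.50,26.33,26.33,26.39,-0.38,-0.582,0.00
BRRI hybrid dhan3,27.27,27.47,27.47,27.40,0.63,0.696,0.00
BRRI hybrid dhan5,28.27,28.27,28.13,28.22,1.45,-0.342,0.01
TejGold,25.47,25.47,25.47,25.47,-1.3,-0.001,0.00
JhonokRaj,27.50,28.50,28.30,28.10,1.33,2.974,0.11
Heera-2,27.80,28.00,28.10,27.97,1.2,0.952,0.00
Gold,26.93,27.20,27.30,27.14,0.37,1.184,0.00
Teea,26.83,26.83,26.73,26.80,0.03,-0.257,0.00
SL8H,25.33,25.33,25.70,25.46,-1.31,0.937,0.04
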