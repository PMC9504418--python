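genotype,Barisal,Gazipur,Ishwardi,overall_mean,pi,bi,s2di
BRRI35A x BRRI36R,11.37,10.67,10.67,10.90,-0.65,7.418,0.00
BRRI99A x BRRI36R,11.77,11.63,10.90,11.43,-0.12,5.061,0.28
BRRI35A x BRRI49R,8.800,8.800,9.467,9.022,-2.528,-3.318,0.23
BRRI99A x BRRI49R,12.47,12.20,11.80,12.16,0.61,4.815,0.09
IR79156A x BRRI49R,11.00,11.10,11.77,11.29,-0.26,-4.377,0.23
BRRI35A x BRRI37R,9.833,10.70,10.70,10.41,-1.14,-9.186,0.00
BRRI48A x BRRI38R,12.17,11.87,11.30,11.78,0.23,5.998,0.17
BRRI99A x BRRI38R,10.63,10.80,10.73,10.72,-0.83,-1.436,0.00
IR79156A x BRRI38R,10.13,11.80,12.27,11.40,-0.15,-19.987,0.15
IR79156A x R line7,10.27,11.00,11.93,11.07,-0.48,-12.417,0.48
BRRI35A x BRRI45R,11.57,11.67,11.40,11.54,-0.01,0.266,0.04
BRRI99A x BRRI45R,12.10,11.93,11.83,11.96,0.41,2.263,0.01
IR79156A x BRRI45R,12.20,12.47,11.97,12.21,0.66,-0.340,0.12
BRRI35A x BRRI52R,12.23,11.97,11.77,11.99,0.44,3.820,0.02
BRRI99A x BRRI31R,12.50,11.87,11.17,11.84,0.29,10.194,0.27
IR79156A x BRRI31R,11.43,10.93,11.57,11.31,-0.24,2.148,0.20
H-2264,11.93,11.73,11.97,11.88,0.33,0.958,0.03
H-386,12.93,11.80,11.97,12.23,0.68,11.182,0.01
BRRI hybrid dhan3,12.17,12.27,11.87,12.10,0.55,0.929,0.08
BRRI hybrid dhan5,12.00,11.93,11.97,11.97,0.42,0.540,0.00
TejGold,12.80,12.77,12.60,12.72,1.17,1.182,0.01
JhonokRaj,12.07,12.00,12.07,12.04,0.49,0.374,0.00
Heera-2,12.00,11.47,11.60,11.69,0.14,4.988,0.01
Gold,12.33,11.77,11.87,11.99,0.44,5.508,0.00
Teea,11.33,10.87,10.87,11.02,-0.53,4.945,0.00
SL8H,12.00,11.53,11.63,11.72,0.17,4.448,0.00
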