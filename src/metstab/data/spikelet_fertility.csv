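genotype,Barisal,Gazipur,Ishwardi,overall_mean,pi,bi,s2di
BRRI35A x BRRI36R,86.17,85.60,85.10,85.62,-0.39,-1.559,0.02
BRRI99A x BRRI36R,86.67,89.63,90.97,89.09,3.08,6.152,1.08
BRRI35A x BRRI49R,85.30,84.93,85.60,85.28,-0.73,0.554,0.15
BRRI99A x BRRI49R,87.07,86.50,88.30,87.29,1.28,2.070,0.72
IR79156A x BRRI49R,80.73,83.50,85.17,83.13,-2.88,6.405,0.70
BRRI35A x BRRI37R,85.33,87.33,87.33,86.67,0.66,2.730,0.97
BRRI48A x BRRI38R,89.50,86.50,86.10,87.37,1.36,-4.720,1.84
BRRI99A x BRRI38R,85.13,85.43,87.50,86.02,0.01,3.673,0.25
IR79156A x BRRI38R,86.43,87.10,86.83,86.79,0.78,0.491,0.17
IR79156A x R line7,83.37,86.40,86.40,85.39,-0.62,4.139,2.24
BRRI35A x BRRI45R,85.73,84.73,84.73,85.07,-0.94,-1.361,0.25
BRRI99A x BRRI45R,87.27,87.77,87.77,87.60,1.59,0.684,0.06
IR79156A x BRRI45R,86.30,85.73,85.73,85.92,-0.09,-0.770,0.08
BRRI35A x BRRI52R,85.80,85.23,85.23,85.42,-0.59,-0.770,0.08
BRRI99A x BRRI31R,86.90,86.90,87.07,86.96,0.95,0.265,0.00
IR79156A x BRRI31R,85.80,85.40,85.40,85.53,-0.48,-0.543,0.04
H-2264,83.17,81.83,82.83,82.61,-3.4,-0.238,0.95
H-386,83.47,83.37,84.83,83.89,-2.12,2.180,0.26
BRRI hybrid dhan3,88.53,88.47,87.80,88.27,2.26,-1.141,0.03
BRRI hybrid dhan5,89.40,89.30,89.63,89.44,3.43,0.392,0.02
TejGold,85.60,86.60,86.70,86.30,0.29,1.524,0.21
JhonokRaj,85.53,86.53,87.50,86.52,0.51,2.891,0.03
Heera-2,84.67,86.60,86.67,85.98,-0.03,2.744,0.87
Gold,85.83,84.93,84.87,85.21,-0.8,-1.330,0.18
Teea,84.03,84.03,84.90,84.32,-1.69,1.370,0.07
SL8H,84.50,84.67,84.67,84.61,-1.4,0.230,0.01
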