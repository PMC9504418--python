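genotype,Barisal,Gazipur,Ishwardi,overall_mean,pi,bi,s2di
BRRI35A x BRRI36R,7.743,8.173,8.310,8.076,-0.613,1.714,0.01
BRRI99A x BRRI36R,8.300,9.673,9.673,9.216,0.527,4.244,0.23
BRRI35A x BRRI49R,7.313,7.757,8.623,7.898,-0.791,3.814,0.06
BRRI99A x BRRI49R,8.640,8.790,9.490,8.973,0.284,2.438,0.07
IR79156A x BRRI49R,6.297,7.630,8.930,7.619,-1.07,7.787,0.02
BRRI35A x BRRI37R,6.253,8.853,8.963,8.023,-0.666,8.345,0.74
BRRI48A x BRRI38R,9.370,8.487,8.460,8.772,0.083,-2.805,0.09
BRRI99A x BRRI38R,9.927,8.927,9.583,9.479,0.79,-1.238,0.43
IR79156A x BRRI38R,8.977,9.143,9.087,9.069,0.38,0.355,0.01
IR79156A x R line7,7.650,9.063,8.997,8.570,-0.119,4.179,0.28
BRRI35A x BRRI45R,8.420,8.520,8.523,8.488,-0.201,0.319,0.00
BRRI99A x BRRI45R,9.510,9.417,9.233,9.387,0.698,-0.805,0.00
IR79156A x BRRI45R,9.623,8.817,8.770,9.070,0.381,-2.624,0.07
BRRI35A x BRRI52R,8.317,8.590,8.543,8.483,-0.206,0.713,0.01
BRRI99A x BRRI31R,9.367,9.103,9.257,9.242,0.553,-0.381,0.03
IR79156A x BRRI31R,8.380,8.980,9.150,8.837,0.148,2.334,0.02
H-2264,8.143,8.687,8.617,8.482,-0.207,1.482,0.05
H-386,9.363,8.383,8.333,8.693,0.004,-3.169,0.10
BRRI hybrid dhan3,8.793,8.780,8.847,8.807,0.118,0.147,0.00
BRRI hybrid dhan5,9.857,9.470,9.617,9.648,0.959,-0.781,0.04
TejGold,8.287,8.320,8.313,8.307,-0.382,0.084,0.00
JhonokRaj,8.500,8.810,8.833,8.714,0.025,1.024,0.01
Heera-2,8.557,8.873,8.890,8.773,0.084,1.026,0.01
Gold,8.713,8.553,8.467,8.578,-0.111,-0.739,0.00
Teea,8.087,8.457,8.497,8.347,-0.342,1.256,0.01
SL8H,8.960,8.060,8.083,8.368,-0.321,-2.715,0.11
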