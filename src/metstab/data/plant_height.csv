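genotype,Barisal,Gazipur,Ishwardi,overall_mean,pi,bi,s2di
BRRI35A x BRRI36R,107.3,107.3,107.7,107.4,-2.8,0.377,0.01
BRRI99A x BRRI36R,105.7,107.0,109.3,107.3,-2.9,2.778,3.67
BRRI35A x BRRI49R,108.3,109.0,109.3,108.9,-1.3,0.439,0.44
BRRI99A x BRRI49R,108.3,107.3,109.7,108.4,-1.8,2.563,0.00
IR79156A x BRRI49R,109.7,110.3,113.3,111.1,0.9,3.476,2.60
BRRI35A x BRRI37R,108.7,107.3,108.3,108.1,-2.1,1.013,0.53
BRRI48A x BRRI38R,109.0,109.3,109.0,109.1,-1.1,-0.351,0.02
BRRI99A x BRRI38R,110.3,108.3,108.7,109.1,-1.1,0.193,2.28
IR79156A x BRRI38R,111.3,111.3,112.7,111.8,1.6,1.516,0.23
IR79156A x R line7,113.3,111.3,114.3,113.7,3.5,1.137,0.13
BRRI35A x BRRI45R,110.3,109.7,110.0,110.0,-0.2,0.316,0.18
BRRI99A x BRRI45R,108.7,18.3,110.3,109.1,-1.1,2.245,0.20
IR79156A x BRRI45R,111.0,112.3,111.7,111.7,1.5,-0.638,0.72
BRRI35A x BRRI52R,109.3,109.3,110.3,109.7,-0.5,1.137,0.13
BRRI99A x BRRI31R,109.0,107.3,109.7,108.7,-1.5,2.501,0.28
IR79156A x BRRI31R,112.7,112.7,113.0,112.8,2.6,0.377,0.01
H-2264,115.3,114.0,116.0,115.1,4.9,2.152,0.14
H-386,117.7,118.0,118.0,117.9,7.7,0.029,0.07
BRRI hybrid dhan3,110.0,109.7,110.0,109.9,-0.3,0.347,0.02
BRRI hybrid dhan5,110.0,109.3,110.3,109.9,-0.3,1.075,0.04
TejGold,110.0,108.3,108.7,109.0,-1.2,0.223,1.53
JhonokRaj,109.0,109.0,110.0,109.3,-0.9,1.137,0.13
Heera-2,111.0,109.7,109.7,110.1,-0.1,-0.125,1.18
Gold,110.7,109.3,109.7,109.9,-0.3,0.254,0.93
Teea,109.3,108.7,109.0,109.0,-1.2,0.316,0.18
SL8H,108.3,107.7,109.0,108.3,-1.9,1.455,0.01
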