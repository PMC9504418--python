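genotype,Barisal,Gazipur,Ishwardi,overall_mean,pi,bi,s2di
BRRI35A x BRRI36R,144.3,146.3,146.7,145.8,-3.3,0.631,0.00
BRRI99A x BRRI36R,144.0,148.7,149.3,147.3,-1.8,1.452,0.01
BRRI35A x BRRI49R,146.3,158.3,157.7,154.1,5,3.308,3.37
BRRI99A x BRRI49R,102.7,146.7,148.0,132.4,-16.7,12.802,18.61
IR79156A x BRRI49R,146.7,151.7,152.7,150.3,1.2,1.607,0.00
BRRI35A x BRRI37R,147.3,148.3,150.0,148.6,-0.5,0.584,0.91
BRRI48A x BRRI38R,149.3,150.0,149.3,149.6,0.5,0.072,0.26
BRRI99A x BRRI38R,150.0,150.7,150.3,150.3,1.2,0.131,0.09
IR79156A x BRRI38R,149.7,149.3,152.3,150.4,1.3,0.442,3.85
IR79156A x R line7,150.7,150.0,151.0,150.6,1.5,-0.011,0.52
BRRI35A x BRRI45R,152.7,155.0,157.3,155.0,5.9,1.084,1.49
BRRI99A x BRRI45R,153.3,153.3,155.7,154.1,5,0.418,2.24
IR79156A x BRRI45R,154.0,153.7,152.7,153.4,4.3,-0.274,0.37
BRRI35A x BRRI52R,147.3,147.0,147.3,147.2,-1.9,-0.035,0.07
BRRI99A x BRRI31R,147.3,150.3,149.0,148.9,-0.2,0.619,1.46
IR79156A x BRRI31R,145.3,147.7,147.0,146.7,-2.4,0.547,0.50
H-2264,148.7,149.3,150.7,149.6,0.5,0.429,0.61
H-386,149.7,152.0,151.0,150.9,1.8,0.488,0.84
BRRI hybrid dhan3,146.0,146.0,147.7,146.6,-2.5,0.298,1.15
BRRI hybrid dhan5,147.7,147.0,148.0,147.6,-1.5,-0.011,0.52
TejGold,145.3,145.7,147.0,146.0,-3.1,0.334,0.67
JhonokRaj,151.0,152.3,154.3,152.6,3.5,0.739,1.27
Heera-2,155.3,156.7,156.3,156.1,7,0.322,0.14
Gold,148.3,148.7,149.3,148.8,-0.3,0.215,0.16
Teea,144.0,144.0,144.7,144.2,-4.9,0.120,0.19
SL8H,150.0,150.0,148.3,149.4,0.3,-0.298,1.15
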