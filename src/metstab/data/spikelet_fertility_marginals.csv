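statistic,Barisal,Gazipur,Ishwardi,overall
mean,85.70,85.96,86.37,86.01
ij,-0.31,-0.05,0.36,
cv_percent,1.5,1.9,1.8,
lsd_05,2.09,2.65,2.50,
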