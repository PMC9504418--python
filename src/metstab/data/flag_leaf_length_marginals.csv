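statistic,Barisal,Gazipur,Ishwardi,overall
mean,29.62,29.87,30.03,29.84
ij,-0.22,0.03,0.19,
cv_percent,2.6,2.5,2.3,
lsd_05,1.26,1.24,1.14,
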