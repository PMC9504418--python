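statistic,Barisal,Gazipur,Ishwardi,overall
mean,26.59,26.82,26.90,26.77
ij,-0.18,0.05,0.13,
cv_percent,1.1,1.3,1.5,
lsd_05,0.49,0.56,0.66,
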