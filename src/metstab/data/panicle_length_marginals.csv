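statistic,Barisal,Gazipur,Ishwardi,overall
mean,27.54,28.03,28.18,27.91
ij,-0.37,0.12,0.27,
cv_percent,1.5,1.8,1.8,
lsd_05,0.67,0.81,0.83,
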