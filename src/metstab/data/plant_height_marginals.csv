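statistic,Barisal,Gazipur,Ishwardi,overall
mean,110.2,109.8,110.7,110.2
ij,0,-0.4,0.5,
cv_percent,1.8,1.9,1.5,
lsd_05,3.19,3.40,2.78,
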