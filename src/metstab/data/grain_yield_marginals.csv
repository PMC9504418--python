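statistic,Barisal,Gazipur,Ishwardi,overall
mean,8.513,8.704,8.850,8.689
ij,-0.176,0.015,0.161,0
cv_percent,2.7,3.2,3.7,
lsd_05,0.37,0.45,0.53,
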