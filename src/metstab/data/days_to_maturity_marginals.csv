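statistic,Barisal,Gazipur,Ishwardi,overall
mean,149.9,146.8,150.5,149.1
ij,0.8,-2.3,1.4,
cv_percent,9.9,1.1,1.0,
lsd_05,23.7,2.76,2.50,
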