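statistic,Barisal,Gazipur,Ishwardi,overall
mean,11.62,11.52,11.52,11.55
ij,0.07,-0.03,-0.03,
cv_percent,6.0,5.6,5.8,
lsd_05,1.14,1.07,1.09,
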