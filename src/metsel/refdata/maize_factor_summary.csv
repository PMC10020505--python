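regime,factor,eigenvalue,variance_pct,cumulative_pct
optimal,1,4.54,37.83,37.83
optimal,2,2.51,20.93,58.77
optimal,3,1.21,10.10,68.86
drought,1,3.47,28.90,28.90
drought,2,2.21,18.38,47.28
drought,3,1.43,11.94,59.22
drought,4,1.25,10.39,69.61
waterlogging,1,4.16,34.64,34.64
waterlogging,2,2.40,20.02,54.66
waterlogging,3,1.47,12.26,66.92
waterlogging,4,1.14,9.52,76.43
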