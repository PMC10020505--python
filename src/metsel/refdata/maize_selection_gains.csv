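regime,trait,factor,sense,goal,xo,xs,sd,sd_pct
optimal,PH,1,increase,yes,170.96,174.14,3.18,1.86
optimal,EH,1,increase,yes,90.66,92.67,2.01,2.22
optimal,SPAD,1,increase,yes,48.30,49.05,0.75,1.55
optimal,EL,1,increase,yes,18.26,18.63,0.37,2.02
optimal,KNR,1,increase,yes,33.73,34.22,0.49,1.46
optimal,GY,1,increase,yes,7.87,8.74,0.87,11.09
optimal,D50A,2,decrease,yes,67.18,66.18,-1.00,-1.48
optimal,D50S,2,decrease,yes,69.60,68.59,-1.02,-1.46
optimal,ASI,2,decrease,yes,2.42,2.42,-0.01,-0.23
optimal,TW,2,increase,yes,29.05,29.82,0.77,2.65
optimal,EG,3,increase,yes,4.34,4.41,0.07,1.58
optimal,KRE,3,increase,yes,14.80,15.20,0.40,2.70
drought,TW,1,increase,yes,25.36,25.28,0.08,0.32
drought,EL,1,increase,yes,16.79,17.13,0.34,2.05
drought,KNR,1,increase,yes,31.82,33.13,1.31,4.11
drought,GY,1,increase,yes,4.39,4.90,0.51,11.67
drought,D50A,2,decrease,yes,89.30,88.47,-0.83,-0.93
drought,D50S,2,decrease,yes,95.00,94.48,-0.52,-0.54
drought,ASI,2,decrease,yes,5.71,5.58,-0.13,-2.28
drought,EG,3,increase,yes,3.99,4.04,0.05,1.17
drought,KRE,3,increase,yes,14.72,14.98,0.26,1.76
drought,PH,4,increase,yes,151.36,153.83,2.47,1.63
drought,EH,4,increase,yes,91.25,96.72,5.47,6.00
drought,SPAD,4,increase,yes,39.14,40.22,1.09,2.77
waterlogging,SPAD,1,increase,yes,25.04,28.52,3.48,13.90
waterlogging,TW,1,increase,yes,25.10,25.62,0.52,2.07
waterlogging,EL,1,increase,yes,13.92,14.25,0.33,2.40
waterlogging,KNR,1,increase,yes,25.84,27.31,1.47,5.68
waterlogging,GY,1,increase,yes,3.80,4.65,0.86,22.59
waterlogging,D50A,2,decrease,yes,56.33,55.97,-0.36,-0.64
waterlogging,PH,2,increase,yes,138.49,141.44,2.95,2.13
waterlogging,EH,2,increase,yes,76.56,78.60,2.03,2.66
waterlogging,EG,3,increase,yes,3.93,4.04,0.11,2.79
waterlogging,KRE,3,increase,yes,14.23,14.60,0.37,2.61
waterlogging,D50S,4,decrease,yes,61.23,60.74,-0.48,-0.79
waterlogging,ASI,4,decrease,yes,4.89,4.69,-0.20,-4.06
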