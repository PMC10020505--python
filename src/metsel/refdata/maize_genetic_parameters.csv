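regime,trait,lrt_g,lrt_ge,sigma2_p,r2ge,h2mg,accuracy,cv_g,cv_r,cv_ratio
optimal,D50A,95.49,12.33,4.60,0.12,0.93,0.96,2.32,1.72,1.34
optimal,D50S,83.10,19.17,5.80,0.16,0.92,0.96,2.40,1.77,1.36
optimal,ASI,0.15,29.43,1.09,0.39,0.16,0.40,5.79,32.47,0.17
optimal,PH,6.60,112.39,297.50,0.59,0.61,0.78,3.91,4.87,0.81
optimal,EH,45.10,14.14,169.0,0.18,0.86,0.93,8.68,9.21,0.94
optimal,SPAD,0.87,167.65,33.57,0.72,0.33,0.57,2.86,5.63,0.50
optimal,EL,7.06,144.21,2.03,0.62,0.62,0.78,3.15,3.56,0.89
optimal,EG,8.14,145.25,0.12,0.60,0.63,0.79,3.33,3.67,0.91
optimal,KRE,14.94,175.24,1.39,0.58,0.73,0.85,4.00,3.23,1.24
optimal,KNR,1.57,239.05,12.67,0.79,0.40,0.63,2.95,3.71,0.79
optimal,TW,7.09,258.82,5.89,0.70,0.61,0.78,3.49,2.92,1.19
optimal,GY,18.19,274.26,2.08,0.62,0.75,0.86,9.76,5.27,1.85
drought,D50A,10.31,8.71,7.10,0.21,0.54,0.73,1.54,2.11,0.72
drought,D50S,1.89,2.52,5.12,0.15,0.29,0.53,0.73,1.92,0.38
drought,ASI,4.18,23.14,3.87,0.35,0.38,0.62,14.56,23.31,0.62
drought,PH,34.01,1.12,195.3,0.06,0.78,0.88,6.09,5.71,1.06
drought,EH,21.91,10.65,186.2,0.19,0.68,0.83,9.41,9.11,1.03
drought,SPAD,9.10,9.47,19.16,0.23,0.51,0.31,5.59,7.81,0.71
drought,EL,4.39,30.36,2.04,0.39,0.38,0.62,3.71,5.48,0.68
drought,EG,2.11,67.28,0.11,0.58,0.30,0.53,3.17,4.29,0.74
drought,KRE,16.02,45.13,1.68,0.35,0.61,0.78,5.45,4.53,1.20
drought,KNR,5.61,44.53,11.42,0.44,0.42,0.65,5.04,6.11,0.83
drought,TW,8.26,57.25,5.05,0.46,0.49,0.70,4.96,4.33,1.09
drought,GY,13.85,138.34,0.96,0.50,0.59,0.76,13.96,7.17,1.95
waterlogging,D50A,7.80,20.1,9.15,0.33,0.77,0.88,2.66,3.36,0.79
waterlogging,D50S,1.61,47.31,13.33,0.54,0.55,0.74,2.06,3.37,0.61
waterlogging,ASI,0.68,89.31,4.77,0.66,0.43,0.65,12.93,22.46,0.57
waterlogging,PH,9.08,0.76,233.0,0.08,0.81,0.89,4.86,8.01,0.61
waterlogging,EH,4.33,1.00,148.7,0.09,0.71,0.84,5.92,12.56,0.47
waterlogging,SPAD,17.76,57.76,26.73,0.37,0.86,0.93,13.24,9.67,1.37
waterlogging,EL,12.55,144.24,2.38,0.52,0.82,0.91,6.78,3.61,1.88
waterlogging,EG,11.58,72.56,0.11,0.45,0.81,0.90,4.87,3.77,1.29
waterlogging,KRE,6.57,161.57,2.20,0.62,0.74,0.86,5.48,3.44,1.60
waterlogging,KNR,10.42,161.26,13.06,0.56,0.78,0.89,8.21,4.38,1.88
waterlogging,TW,5.05,105.18,6.34,0.59,0.71,0.84,4.81,3.95,1.22
waterlogging,GY,12.99,196.68,1.45,0.55,0.83,0.91,19.74,7.88,2.51
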