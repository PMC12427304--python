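feature,stat,vocalization,negative,positive_neutral,oral_manipulation,physical_contact,alert,sneezing,coughing
n,n,1167,296,380,45,123,51,319,81
sum_ai,mean,14.55,25.70,2.99,13.81,27.33,24.88,20.46,3.42
sum_ai,q1,1.80,2.71,1.09,2.68,3.12,6.09,5.18,1.57
sum_ai,med,4.00,5.63,1.68,5.41,6.94,11.82,8.88,2.41
sum_ai,q3,10.34,15.88,2.83,12.08,15.30,23.27,20.48,4.10
a_bar,mean,24.25,27.44,19.37,27.43,28.30,21.63,27.78,24.65
a_bar,q1,20.31,23.62,16.58,23.89,24.73,19.57,26.18,22.55
a_bar,med,24.42,28.27,19.37,27.87,29.24,21.88,28.08,24.42
a_bar,q3,28.50,31.41,21.77,31.24,31.93,23.00,29.44,26.37
var,mean,39.64,71.25,14.06,39.96,74.01,145.22,34.53,10.62
var,q1,6.42,7.32,5.04,6.52,8.29,28.43,8.57,5.10
var,med,11.30,16.63,7.86,13.22,17.18,69.32,14.11,6.95
var,q3,24.69,36.34,12.56,25.39,36.71,132.71,32.94,12.29
q1,mean,396.26,421.32,147.83,407.81,429.94,373.63,744.50,239.58
q1,q1,81.03,103.08,65.81,80.39,99.25,282.17,155.39,64.31
q1,med,97.07,238.31,97.98,260.06,288.49,370.87,449.46,172.28
q1,q3,445.43,630.80,232.76,452.41,659.25,442.52,1314.86,374.86
q2,mean,1017.67,1073.32,319.41,1034.70,1084.53,652.31,2003.6,693.39
q2,q1,298.78,341.38,238.27,361.91,398.70,479.62,1078.14,437.36
q2,med,538.36,870.07,304.47,888.47,947.00,581.77,1936.33,599.37
q2,q3,1494.33,1461.60,339.66,1517.47,1378.16,761.64,2808.91,906.52
q3,mean,2113.61,2287.67,663.51,2454.58,2271.59,997.44,4127.72,1529.76
q3,q1,593.67,1048.97,348.58,958.05,1176.08,704.80,2945.18,1246.30
q3,med,1386.88,1803.91,399.03,2268.11,2105.52,789.55,4244.95,1554.74
q3,q3,3339.61,3448.64,786.19,3754.37,3255.79,1207.50,5142.95,1785.54
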