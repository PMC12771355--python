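timepoint,method,n,mean,sd,ci_low,ci_high
1,test,55,2.77,0.46,2.64,2.89
1,reference,55,2.76,0.48,2.63,2.89
2,test,55,2.39,0.40,2.28,2.50
2,reference,55,2.38,0.36,2.29,2.48
3,test,55,2.57,0.43,2.45,2.68
3,reference,55,2.50,0.42,2.39,2.61
4,test,54,2.54,0.48,2.41,2.67
4,reference,54,2.54,0.50,2.40,2.68
5,test,54,3.05,0.40,2.94,3.16
5,reference,54,3.02,0.40,2.91,3.13
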