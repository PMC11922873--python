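drug,endpoint,n,ror,ror_low,ror_high,ic,ic025,ebgm,ebgm05
BSZ,dyskinesia,342,16.5,14.76,18.45,3.91,3.75,15.03,13.69
BSZ,on_off_phenomenon,157,170.74,145.03,201.01,7.29,7.06,156.65,136.65
BSZ,freezing_phenomenon,77,104.35,83.01,131.17,6.64,6.31,99.47,82.14
BSZ,wearing_off,64,3.03,2.37,3.88,1.58,1.23,3.0,2.44
CD,dyskinesia,1214,13.81,13.02,14.65,3.66,3.58,12.65,12.04
CD,on_off_phenomenon,261,67.5,59.46,76.63,5.95,5.77,61.75,55.53
CD,freezing_phenomenon,279,96.36,85.07,109.14,6.42,6.24,85.46,77.0
CD,wearing_off,660,7.66,7.08,8.28,2.87,2.76,7.33,6.86
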