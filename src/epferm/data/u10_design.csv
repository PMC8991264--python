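run,glycerol,yeast_powder,peptone,znso4,mgso4,kh2po4,ep_28h,ep_56h,ep_84h,ep_112h
1,4.5,0.5,0.2,0.035,0.06,0.18,28.43,244.67,177.83,44.42
2,3.5,0.2,0.35,0.025,0.24,0.2,40.49,227.96,147.46,53.16
3,5,0.25,0.55,0.005,0.08,0.14,32.85,139.16,139.41,84.86
4,2,0.4,0.25,0.01,0.18,0.12,24.3,195.99,160.97,69.85
5,6,0.3,0.3,0.045,0.14,0.08,28.37,106.63,63.58,48.71
6,2.5,0.35,0.6,0.04,0.12,0.22,33.39,157.66,99.04,64.24
7,5.5,0.45,0.65,0.03,0.22,0.1,34.42,136.68,147.17,99.00
8,3,0.6,0.45,0.02,0.1,0.06,17.21,49.36,105.80,90.09
9,6.5,0.55,0.4,0.015,0.16,0.24,25.3,156.57,108.10,75.87
10,4,0.65,0.5,0.05,0.2,0.16,29.94,192.52,118.74,96.68
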