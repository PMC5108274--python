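class,tau_lon,tau_lat,nu_lon,nu_lat
3,0.00360,0.00252,3.8,4.0
2,0.00541,0.00379,3.0,3.2
1,0.00973,0.00681,2.5,2.6
0,0.03251,0.02276,2.0,2.1
A,0.01500,0.01050,2.0,2.1
B,0.02760,0.01932,1.8,1.9
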