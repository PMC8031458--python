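substance,delta_d,delta_p,delta_h,delta_total
SIM,46.60,6.60,5.70,18.70
T80,14.80,8.60,12.70,21.30
T20,14.90,9.40,13.30,22.10
M52,16.10,3.90,7.90,18.40
M59,16.10,3.90,7.90,18.40
B35,9.00,9.70,13.50,18.90
B58,10.10,8.80,12.60,18.40
H2O,15.50,16.00,42.30,47.80
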