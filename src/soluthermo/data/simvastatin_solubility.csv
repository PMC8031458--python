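sample_id,surfactant,conc_mM,T_K,x_e
H2O,water,0,300.2,7.57e-07
H2O,water,0,310.2,1.29e-06
H2O,water,0,320.2,1.94e-06
1 mM T80,T80,1,300.2,9.37e-05
1 mM T80,T80,1,310.2,1.29e-04
1 mM T80,T80,1,320.2,1.77e-04
5 mM T80,T80,5,300.2,5.00e-04
5 mM T80,T80,5,310.2,6.36e-04
5 mM T80,T80,5,320.2,8.27e-04
10 mM T80,T80,10,300.2,7.34e-04
10 mM T80,T80,10,310.2,9.32e-04
10 mM T80,T80,10,320.2,1.18e-03
20 mM T80,T80,20,300.2,1.08e-03
20 mM T80,T80,20,310.2,1.35e-03
20 mM T80,T80,20,320.2,1.68e-03
1 mM T20,T20,1,300.2,4.69e-05
1 mM T20,T20,1,310.2,6.42e-05
1 mM T20,T20,1,320.2,8.80e-05
5 mM T20,T20,5,300.2,1.94e-04
5 mM T20,T20,5,310.2,2.52e-04
5 mM T20,T20,5,320.2,3.31e-04
10 mM T20,T20,10,300.2,4.84e-04
10 mM T20,T20,10,310.2,6.45e-04
10 mM T20,T20,10,320.2,8.06e-04
20 mM T20,T20,20,300.2,7.18e-04
20 mM T20,T20,20,310.2,9.13e-04
20 mM T20,T20,20,320.2,1.16e-03
1 mM M52,M52,1,300.2,2.75e-04
1 mM M52,M52,1,310.2,3.72e-04
1 mM M52,M52,1,320.2,4.78e-04
5 mM M52,M52,5,300.2,1.54e-03
5 mM M52,M52,5,310.2,1.90e-03
5 mM M52,M52,5,320.2,2.33e-03
10 mM M52,M52,10,300.2,3.60e-03
10 mM M52,M52,10,310.2,4.29e-03
10 mM M52,M52,10,320.2,5.20e-03
20 mM M52,M52,20,300.2,4.67e-03
20 mM M52,M52,20,310.2,5.62e-03
20 mM M52,M52,20,320.2,6.56e-03
1 mM M59,M59,1,300.2,4.92e-04
1 mM M59,M59,1,310.2,6.61e-04
1 mM M59,M59,1,320.2,9.17e-04
5 mM M59,M59,5,300.2,2.28e-03
5 mM M59,M59,5,310.2,2.84e-03
5 mM M59,M59,5,320.2,3.54e-03
10 mM M59,M59,10,300.2,6.01e-03
10 mM M59,M59,10,310.2,7.03e-03
10 mM M59,M59,10,320.2,8.44e-03
20 mM M59,M59,20,300.2,1.15e-02
20 mM M59,M59,20,310.2,1.33e-02
20 mM M59,M59,20,320.2,1.54e-02
1 mM B35,B35,1,300.2,1.35e-04
1 mM B35,B35,1,310.2,1.87e-04
1 mM B35,B35,1,320.2,2.53e-04
5 mM B35,B35,5,300.2,3.43e-04
5 mM B35,B35,5,310.2,5.48e-04
5 mM B35,B35,5,320.2,8.15e-04
10 mM B35,B35,10,300.2,1.13e-03
10 mM B35,B35,10,310.2,1.39e-03
10 mM B35,B35,10,320.2,1.76e-03
20 mM B35,B35,20,300.2,2.71e-03
20 mM B35,B35,20,310.2,3.25e-03
20 mM B35,B35,20,320.2,3.97e-03
1 mM B58,B58,1,300.2,9.11e-05
1 mM B58,B58,1,310.2,1.37e-04
1 mM B58,B58,1,320.2,1.94e-04
5 mM B58,B58,5,300.2,2.55e-04
5 mM B58,B58,5,310.2,3.36e-04
5 mM B58,B58,5,320.2,4.55e-04
10 mM B58,B58,10,300.2,4.34e-04
10 mM B58,B58,10,310.2,5.57e-04
10 mM B58,B58,10,320.2,7.55e-04
20 mM B58,B58,20,300.2,3.74e-03
20 mM B58,B58,20,310.2,4.47e-03
20 mM B58,B58,20,320.2,5.52e-03
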