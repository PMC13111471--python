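name,concentration_mg_ml,mw_mda,crosslinked,g_prime_pa,eta_pa_s,tan_delta
HA-A,10,0.5,false,80,30,0.2
HA-B,15,1.2,false,150,65,0.45
HA-C,20,2.0,false,190,100,0.5
HA-D,30,3.0,true,260,180,0.7
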