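subject,accuracy_pct,max_force_N,max_torque_Nm
Y_R,91.67,1.86,0.38
Y_S,100.00,5.91,2.65
Y_T,100.00,5.27,5.89
Y_U,95.83,4.44,3.57
Y_V,100.00,4.09,3.82
Y_W,95.83,1.88,2.61
Y_X,100.00,5.90,4.69
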