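subject,accuracy_pct,max_force_N,max_torque_Nm
A,91.67,1.79,4.13
B,91.67,2.53,7.03
C,91.67,1.90,5.55
D,87.50,8.84,10.05
I,91.67,1.05,2.14
K,91.67,3.58,7.45
L,83.33,2.12,6.91
M,91.67,3.00,6.45
N,87.50,0.97,1.92
O,91.67,7.01,8.75
P,91.67,1.67,3.58
Q,95.83,2.84,7.10
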