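anode	cathode
Fp1	Fp2
Fp1	F7
Fp1	F3
Fp1	Fz
Fp2	Fz
Fp2	F4
Fp2	F8
F7	F3
F7	T3
F7	C3
F3	Fz
F3	T3
F3	C3
F3	Cz
Fz	F4
Fz	C3
Fz	Cz
Fz	C4
F4	F8
F4	Cz
F4	C4
F4	T4
F8	C4
F8	T4
T3	C3
T3	T5
T3	P3
C3	Cz
C3	T5
C3	P3
C3	Pz
Cz	C4
Cz	P3
Cz	Pz
Cz	P4
C4	T4
C4	Pz
C4	P4
C4	T6
T4	P4
T4	T6
T5	P3
T5	O1
P3	Pz
P3	O1
Pz	P4
Pz	O1
Pz	O2
P4	T6
P4	O2
T6	O2
O1	O2
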