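element	RfD	RfC	SF	IUR	organs
As	3.0e-4	1.5e-5	1.5	4.3e-3	cardiovascular;skin
Be	2.0e-3	2.0e-5		2.4e-3
Cd	1.0e-3	1.0e-5		1.8e-3	kidney
Co	3.0e-4	6.0e-6		9.0e-3	blood
Cr	3.0e-3	1.0e-4		8.4e-2
Cu	4.0e-2				kidney;gastrointestinal;development
Hg	3.0e-4	3.0e-4			cns;kidney
Mo	5.0e-3				kidney
Ni	2.0e-2	9.0e-5		2.6e-4
Pb	3.5e-3	3.5e-4	8.5e-3	1.2e-5	cns;kidney;cardiovascular;red_blood_cells
Sb	4.0e-4	3.0e-4			gi_tract
Sn	6.0e-1
Tl	1.0e-5
V	5.0e-3	1.0e-4			kidney;gastrointestinal;blood
Zn	3.0e-1				blood
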