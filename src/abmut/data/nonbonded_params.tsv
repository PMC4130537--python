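# Minimal element-keyed nonbonded parameter table (editable).
# epsilon in kcal/mol, rmin_half in Angstrom; generic per-element values of
# the magnitude used by protein force fields. default_charge left blank so
# that charges must be assigned explicitly (no silent zeros).
atom_class	epsilon	rmin_half	default_charge
H	0.046	0.2245
C	0.078	2.040
N	0.170	1.850
O	0.120	1.700
S	0.450	2.000
P	0.585	2.150
F	0.097	1.632
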