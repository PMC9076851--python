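# MM-PBSA binding free energy components (kJ/mol) of four protein-ligand complexes.
# The MAPK1-geniposide polar term is typographically ambiguous in its published
# source; 162.12 is the value consistent with component additivity and is
# flagged by the `ambiguous` column.
complex	vdw	elec	polar	sasa	total	ambiguous
AKT1-reptoside	-158.871	-23.789	78.68	-16.882	-120.861	0
ESR1-aucubin	-144.328	-110.032	184.823	-18.807	-88.345	0
MAPK1-geniposide	-132.831	-64.421	162.12	-17.261	-52.391	1
MAPK3-ajugoside	-148.77	-25.796	108.163	-16.097	-82.499	0
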