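# Hydration free energies of amino-acid side-chain analogs relative to
# methane (the alanine side-chain mimic), kcal/mol.  ddg_exp is the
# experimental relative hydration free energy; calculated columns are
# X -> methane perturbations averaged over 10 replicas with their SEM,
# for both the acceptance-ratio and the exponential-averaging estimator.
mutation,analog,ddg_exp,ddg_calc_bar,sem_bar,ddg_calc_zwanzig,sem_zwanzig
ASN,acetamide,11.62,11.18,0.06,11.18,0.06
CYS,methanethiol,3.18,2.77,0.02,2.77,0.02
GLN,propionamide,11.32,11.46,0.07,11.46,0.07
ILE,1-butane,-0.21,0.13,0.05,0.13,0.05
LEU,isobutane,-0.34,-0.04,0.02,-0.03,0.02
MET,methylsulfanylethane,3.42,2.67,0.06,2.67,0.06
PHE,toluene,2.70,3.47,0.04,3.47,0.04
SER,methanol,7.00,6.99,0.05,6.98,0.05
THR,ethanol,6.82,6.91,0.10,6.91,0.10
TRP,3-methyl-1H-indole,7.82,7.72,0.08,7.72,0.08
TYR,p-cresol,8.05,8.42,0.07,8.43,0.06
VAL,propane,-0.05,0.08,0.02,0.08,0.02
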