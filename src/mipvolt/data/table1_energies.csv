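monomer,e_complex,e_template,e_monomer,units
MBT,-2192.04511,-1071.15051,-1120.88752,KJ/Mol
ETOP,-1852.002872,-1071.15051,-780.840446,KJ/Mol
Py,-1281.328453,-1071.15051,-210.165882,KJ/Mol
H-A,-2704.622198,-1071.15051,-1633.46655,KJ/Mol
OPD,-1414.110633,-1071.15051,-342.955368,KJ/Mol
IPA,-1436.397477,-1071.15051,-365.235993,KJ/Mol
A,-1358.76093,-1071.15051,-287.601785,KJ/Mol
OAP,-1433.979616,-1071.15051,-362.818674,KJ/Mol
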