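# Promolecular single-zeta Slater shell parameters.
# Exponents: Clementi-Raimondi effective single-zeta values per occupied
# subshell (bohr^-1); occupancies: neutral-atom Aufbau configuration,
# subshells of equal n,l merged. Subshells are treated as spherically
# averaged radial densities, so only (n, zeta, occupancy) matter.
# Replace or extend rows to use a different parameterization.
# element  n  zeta(bohr^-1)  occupancy
H   1  1.0000  1
He  1  1.6875  2
Li  1  2.6906  2
Li  2  0.6396  1
Be  1  3.6848  2
Be  2  0.9560  2
B   1  4.6795  2
B   2  1.2881  2
B   2  1.2107  1
C   1  5.6727  2
C   2  1.6083  2
C   2  1.5679  2
N   1  6.6651  2
N   2  1.9237  2
N   2  1.9170  3
O   1  7.6579  2
O   2  2.2458  2
O   2  2.2266  4
F   1  8.6501  2
F   2  2.5638  2
F   2  2.5500  5
Ne  1  9.6421  2
Ne  2  2.8792  2
Ne  2  2.8792  6
Na  1  10.6259 2
Na  2  3.2857  2
Na  2  3.4009  6
Na  3  0.8358  1
Mg  1  11.6089 2
Mg  2  3.6960  2
Mg  2  3.9129  6
Mg  3  1.1025  2
Al  1  12.5910 2
Al  2  4.1068  2
Al  2  4.4817  6
Al  3  1.3724  2
Al  3  1.3552  1
Si  1  13.5745 2
Si  2  4.5100  2
Si  2  4.9725  6
Si  3  1.6344  2
Si  3  1.4284  2
P   1  14.5578 2
P   2  4.9125  2
P   2  5.4806  6
P   3  1.8806  2
P   3  1.6288  3
S   1  15.5409 2
S   2  5.3144  2
S   2  5.9885  6
S   3  2.1223  2
S   3  1.8273  4
Cl  1  16.5239 2
Cl  2  5.7152  2
Cl  2  6.4966  6
Cl  3  2.3561  2
Cl  3  2.0387  5
Ar  1  17.5075 2
Ar  2  6.1152  2
Ar  2  7.0041  6
Ar  3  2.5856  2
Ar  3  2.2547  6
K   1  18.4895 2
K   2  6.5031  2
K   2  7.5136  6
K   3  2.8933  2
K   3  2.5752  6
K   4  0.8738  1
Ca  1  19.4730 2
Ca  2  6.8882  2
Ca  2  8.0207  6
Ca  3  3.2005  2
Ca  3  2.8861  6
Ca  4  1.0995  2
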