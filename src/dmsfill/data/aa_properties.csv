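aa,num_mol_weight,num_isoelectric_point,num_pka_carboxyl,num_pka_amino,num_hydropathy,num_volume,bool_hbond_capable,bool_typically_buried,cat_chemical_group,cat_charge,cat_polarity
A,89.09,6.01,2.34,9.69,1.8,88.6,0,1,aliphatic,neutral,nonpolar
C,121.16,5.07,1.96,10.28,2.5,108.5,1,1,sulfur,neutral,polar
D,133.1,2.77,1.88,9.6,-3.5,111.1,1,0,acidic,negative,polar
E,147.13,3.22,2.19,9.67,-3.5,138.4,1,0,acidic,negative,polar
F,165.19,5.48,1.83,9.13,2.8,189.9,0,1,aromatic,neutral,nonpolar
G,75.07,5.97,2.34,9.6,-0.4,60.1,0,0,aliphatic,neutral,polar
H,155.16,7.59,1.82,9.17,-3.2,153.2,1,0,basic,positive,polar
I,131.17,6.02,2.36,9.6,4.5,166.7,0,1,aliphatic,neutral,nonpolar
K,146.19,9.74,2.18,8.95,-3.9,168.6,1,0,basic,positive,polar
L,131.17,5.98,2.36,9.6,3.8,166.7,0,1,aliphatic,neutral,nonpolar
M,149.21,5.74,2.28,9.21,1.9,162.9,0,1,sulfur,neutral,nonpolar
N,132.12,5.41,2.02,8.8,-3.5,114.1,1,0,amide,neutral,polar
P,115.13,6.48,1.99,10.6,-1.6,112.7,0,0,aliphatic,neutral,nonpolar
Q,146.15,5.65,2.17,9.13,-3.5,143.8,1,0,amide,neutral,polar
R,174.2,10.76,2.17,9.04,-4.5,173.4,1,0,basic,positive,polar
S,105.09,5.68,2.21,9.15,-0.8,89.0,1,0,hydroxylic,neutral,polar
T,119.12,5.87,2.09,9.1,-0.7,116.1,1,0,hydroxylic,neutral,polar
V,117.15,5.97,2.32,9.62,4.2,140.0,0,1,aliphatic,neutral,nonpolar
W,204.23,5.89,2.83,9.39,-0.9,227.8,1,1,aromatic,neutral,nonpolar
Y,181.19,5.66,2.2,9.11,-1.3,193.6,1,0,aromatic,neutral,polar
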