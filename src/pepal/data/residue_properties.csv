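# Per-residue property table for the Judred descriptor set (one row per canonical amino acid).
# mass_free_aa: average molecular mass of the free amino acid, g/mol.
# ww_logp: Wimley-White whole-residue water->octanol transfer free energy converted to a
#   log P contribution, -dG/(2.303*R*T) at 298.15 K; positive = hydrophobic. dG values from
#   Wimley & White, Nat Struct Biol 1996 (octanol scale; D/E/R/K charged, H neutral).
# sp2_carbons: side-chain sp2 carbons plus one backbone carbonyl carbon per residue.
# sp3_carbons: side-chain sp3 carbons plus the backbone alpha carbon (>=1 for every residue).
# nh2_groups: side-chain NH2/NH3 count (K=1, R=2 guanidinium, N/Q amide=1; ring NH excluded).
# oh_groups: side-chain hydroxyls, backbone excluded (S/T/Y).
# s_atoms: sulfur count (C/M).
# side_chain_charge: integer side-chain charge at pH 7 (K/R=+1, D/E=-1, H=0).
# max_asa: theoretical maximum solvent-accessible surface area, A^2 (Tien et al. 2013).
# bulkiness: Zimmerman bulkiness scale (Zimmerman et al. 1968).
residue,mass_free_aa,ww_logp,sp2_carbons,sp3_carbons,nh2_groups,oh_groups,s_atoms,side_chain_charge,max_asa,bulkiness
A,89.094,-0.3664,1,2,0,0,0,0,129.0,11.5
C,121.154,0.0147,1,2,0,0,1,0,167.0,13.46
D,133.103,-2.6677,2,2,0,0,0,-1,193.0,11.68
E,147.13,-2.6603,2,3,0,0,0,-1,223.0,13.57
F,165.192,1.2532,7,2,0,0,0,0,240.0,19.8
G,75.067,-0.8428,1,1,0,0,0,0,104.0,3.4
H,155.156,-1.7076,4,2,0,0,0,0,224.0,13.69
I,131.175,0.8208,1,5,0,0,0,0,197.0,21.4
K,146.189,-2.0520,1,5,1,0,0,1,236.0,15.71
L,131.175,0.9161,1,5,0,0,0,0,201.0,21.4
M,149.208,0.4910,1,4,0,0,1,0,224.0,16.25
N,132.119,-0.6229,2,2,1,0,0,0,195.0,12.82
P,115.132,-0.1026,1,4,0,0,0,0,159.0,17.43
Q,146.146,-0.5643,2,3,1,0,0,0,225.0,14.45
R,174.203,-1.3265,2,4,2,0,0,1,274.0,14.28
S,105.093,-0.3371,1,2,0,1,0,0,155.0,9.47
T,119.12,-0.1832,1,3,0,1,0,0,172.0,15.77
V,117.148,0.3371,1,4,0,0,0,0,174.0,21.57
W,204.229,1.5317,9,2,0,0,0,0,285.0,21.67
Y,181.191,0.5203,7,2,0,1,0,0,263.0,18.03
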