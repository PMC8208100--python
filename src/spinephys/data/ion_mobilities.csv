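species,valence,conductivity,source
K,1,73.5,Robinson & Stokes 1959 (limiting equivalent conductivity at 25 C)
Na,1,50.1,Robinson & Stokes 1959
Cl,-1,76.35,Robinson & Stokes 1959
HCO3,-1,44.5,Robinson & Stokes 1959
H2PO4,-1,36.0,Vanysek CRC Handbook
Mg,2,53.06,Robinson & Stokes 1959
Ca,2,59.5,Robinson & Stokes 1959
gluconate,-1,24.3,Barry & Lynch 1991 (junction-potential literature)
HEPES,-1,22.05,Barry & Lynch 1991
EGTA,-2,24.3,Barry & Lynch 1991
ATP,-2,42.0,Barry & Lynch 1991 (approximate)
GTP,-3,42.0,assumed equal to ATP (negligible contribution)
OH,-1,198.0,Robinson & Stokes 1959
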