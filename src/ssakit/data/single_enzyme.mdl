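# Single-molecule enzyme kinetics with the substrate pool buffered ($S is
# fixed): E + S <-> ES -> E + P.  Effective binding rate k1*S = 0.01*100
# = 1 min^-1; enzyme copy number E + ES = 1 is conserved, so the enzyme is
# either free (1) or bound (0).  Product-formation waiting times follow a
# two-phase (hypoexponential-family) phase-type law.
Rbind: E + $S > ES, 0.01
Runbind: ES > E + $S, 0.5
Rcat: ES > E + P, 1.0
$S = 100
E = 1
ES = 0
P = 0
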