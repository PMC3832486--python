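# Single-molecule enzyme kinetics with a finite, consumable substrate pool:
# E + S <-> ES -> E + P, S not buffered.  Used for product-formation time
# courses that saturate as the substrate is exhausted.
Rbind: E + S > ES, 0.01
Runbind: ES > E + S, 0.5
Rcat: ES > E + P, 1.0
S = 100
E = 1
ES = 0
P = 0
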