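# Immigration-death model: constitutive mRNA synthesis (zero order,
# 10 min^-1) and first-order degradation (0.2 min^-1).
# Stationary law: Poisson with mean ksyn/kd = 50 molecules/cell.
Rsyn: $pool > mRNA, 10.0
Rdeg: mRNA > $pool, 0.2
mRNA = 50
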