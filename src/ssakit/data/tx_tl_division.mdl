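# Transcription-translation network for cell-division case studies.
# A transcription factor is synthesized, degraded, and toggles between an
# inactive (TFi) and active (TFa) form; transcription is a saturating
# (Hill-type, n = 1) function of active TF — the one non-mass-action rate
# law; mRNA is translated and both mRNA and protein decay first order.
# The protein is stable (half-life ~700 min >> the 60 min generation time),
# so its loss is dominated by dilution (implicit model) or partitioning at
# division (explicit model) — under explicit division the protein shows the
# large sawtooth variations that distinguish the two formulations.
# Nine reactions total.  Rates in min^-1; initial state near steady state.
vmax : 2.0
Km : 2.0
Rtfsyn: $pool > TFi, 0.1
Rtfdeg: TFi > $pool, 0.02
Ract: TFi > TFa, 0.1
Rdeact: TFa > TFi, 0.1
Rtfadeg: TFa > $pool, 0.02
Rtxn: $pool > mRNA, vmax*TFa/(Km+TFa)
Rmdeg: mRNA > $pool, 0.1
Rtln: mRNA > mRNA + P, 2.0
Rpdeg: P > $pool, 0.001
TFi = 2
TFa = 2
mRNA = 8
P = 1200
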