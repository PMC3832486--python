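# Two-state (telegraph) gene: promoter toggles ON/OFF, transcription only
# while ON, first-order mRNA decay.  Default constants are the bursty set
# (long ON and OFF dwell times -> transcription bursts, bimodal mRNA
# distribution); the non-bursty set raises kon/koff to 1.
kon : 0.01
koff : 0.01
ksyn : 1.0
kd : 0.05
Ron: Goff > Gon, kon*Goff
Roff: Gon > Goff, koff*Gon
Rsyn: Gon > Gon + mRNA, ksyn*Gon
Rdeg: mRNA > $pool, kd*mRNA
Goff = 1
Gon = 0
mRNA = 0
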