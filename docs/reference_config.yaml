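# ctdsim reference configuration (the shipped defaults).
# Flat key-value YAML; unknown keys are rejected.

# Activator copies
activator: 5
# activator-promoter binding [1/s]
activator_bind: 1.0
# Bur1 copies
bur1: 1
# Ctk1 copies
ctk1: 7
# Ctk1 Ser5-kinase activity: NONE / FROM_UU / FROM_PU / BOTH
ctk1_ser5_variant: FROM_UU
# gene copies (fixed at 1)
dna: 1
# advance rate per 30-nt site [sites/s]
elongation_step: 2.36
# Fcp1 copies
fcp1: 1
# polymerase footprint per DNA site [nt]
footprint_nt: 30
# promoter escape to e1 [1/s]
initiation: 2.0
# Kin28 Ser5+Ser7 phosphorylation per repeat at the promoter [1/s]
kin28: 2.0
# advance rate over pA sites [sites/s]
maturation_step: 2.36
# Mediator copies
mediator: 5
# mediator binding (requires activator) [1/s]
mediator_bind: 1.0
# number of 30-nt elongation sites (gene length / footprint)
n_elongation_sites: 80
# 3' maturation sites traversed before release
n_polyA_sites: 20
# heptad repeats tracked on the CTD
n_repeats: 2
# kinase/phosphatase binding meta-parameter [1/s]
p0: 0.1
# enzyme release/catalysis rate [1/s]
p3: 100.0
# mean exponential pause dwell [s]
pause_duration_mean: 30.0
# elongation-site index of an optional pause (null = none)
pause_site: null
# Pcf11 copies
pcf11: 15
# Pcf11 binding per free copy (requires Ser2~P) [1/s]
pcf11_bind: 0.1
# mature-mRNA release from the last pA site [1/s]
release: 1.0
# RNAPII pool size
rnapii: 20
# RNAPII promoter loading per free unphosphorylated polymerase [1/s]
rnapii_bind: 0.047
# Rtr1 copies
rtr1: 6
# Rtr1 binding rate relative to the Ser2-kinase tier (2.0/1.0/0.5)
rtr1_bind_multiplier: 2.0
# Rtt103 copies
rtt103: 8
# Rtt103 binding per free copy in the 3'-UTR [1/s]
rtt103_bind: 0.1
# Srb10 copies
srb10: 2
# Ssu72 copies
ssu72: 5
# TFIIH copies
tfiih: 5
# TFIIH binding [1/s]
tfiih_bind: 1.0
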