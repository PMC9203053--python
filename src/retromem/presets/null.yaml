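# Null preset: no condition effects, no relatedness coupling, no reminder
# boost.  Condition labels are exchangeable under this generator, so any
# detected cluster or condition difference is a false positive.
n_subjects: 200
delay: 48hr
learning_mode: retrieval
beta0: 0.3
beta_cond:
  NoDelta: 0.0
  DeltaTarget: 0.0
  DeltaCue: 0.0
  DeltaBoth: 0.0
  control: 0.0
beta_rel: 0.0
gamma0: -1.0
gamma1: 0.0
delta: 0.0
rho: 0.0
kappa: 0.0
phi: 0.0
lambda0: 0.3
lambda1: 1.2
iota: 0.2
seed: 0
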