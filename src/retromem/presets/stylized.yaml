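# Stylized generative preset: condition ordering and relatedness effects
# qualitatively match the reported retrieval-to-criterion experiments
# (NoDelta > DeltaCue > DeltaTarget > DeltaBoth > control in base-pair
# memorability for the narrow-range, 48-hr configuration).
n_subjects: 200
delay: 48hr
learning_mode: retrieval
beta0: 0.3
beta_cond:
  NoDelta: 1.0
  DeltaTarget: 0.0
  DeltaCue: 0.4
  DeltaBoth: -0.8
  control: 0.0
beta_rel: 0.5
gamma0: -1.0
gamma1: 2.5
delta: 1.2
rho: 0.6
kappa: 0.6
phi: 0.8
lambda0: 0.3
lambda1: 1.2
iota: 0.2
seed: 0
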