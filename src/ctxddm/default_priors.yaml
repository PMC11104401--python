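# Package-default prior hyperparameters for hierarchical fits.
#
# Baseline group means get uniform priors over the plausible ranges declared
# in the model registry supports (these are package defaults; they also bound
# the subject-level support).  Context-shift group means get Gaussian priors
# centered at 0; group-level dispersions get half-Cauchy priors on the SD.
shift_prior_sd:
  default: 1.0
  # tighter zero-centered priors for parameters living on narrow scales
  eta1: 0.3
  eta2: 0.3
  eta_decay: 0.3
  z: 0.2
  tau: 0.3
  tau_s1: 0.2
  tau_s2: 0.2
  v_coeff: 0.5
sigma_half_cauchy_scale: 2.5
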