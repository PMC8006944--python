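# Default configuration for the identification pipeline and the
# desk-scale in-silico experiment.  CLI flags override these values.
fit:
  error_cv: 0.05            # C-peptide measurement CV (fraction)
  glucose_noise_cv: 0.02    # assumed glucose noise for derivative estimation
  alpha_prior_median: 0.05  # min^-1, weakly-informative provision-rate prior
  alpha_prior_gcv: 0.5
  kinetic_prior_gcv: 0.3    # spread of DB kinetic priors around Van Cauter
  n_starts: 5
  start_jitter: 0.3
  seed: 0
  fine_dt: 1.0              # min
  t_index: 300.0            # min, horizon of the responsivity integrals
  maxiter: 400
insilico:
  replicates: 5             # virtual subjects per source (50 = full scale)
  offset: 1.15              # true kinetics vs Van Cauter prediction
  noise_cv: 0.05
  seed: 1
  n_starts: 2               # multi-start budget of the sweep fits
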