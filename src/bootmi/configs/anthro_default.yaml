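# Editable parameter values for the anthropometric simulation model.
#
# These are placeholder values chosen to satisfy the scenario-defining
# constraints (null sex effects alpha1/iota1/beta1 and eta = 1 unless a
# scenario switches them); replace them with study-specific values to
# reproduce a particular design. Units: age in years, height in cm, weight
# in kg, loginsindex in log units.
pi: 0.5                    # P(sex = 1), sex 1 coded as men
alpha0: [20.0, 170.0]      # mean (age, height) for sex 0
alpha1: [0.0, 0.0]         # sex shift of (age, height); null
Sigma:                     # covariance of (age, height) given sex
  - [1.0, 2.0]
  - [2.0, 36.0]
iota: [-40.0, 0.0, 0.2, 0.6]   # weight: intercept, sex, age, height
lam: 1.0                   # heteroscedasticity exponent for weight errors
beta: [0.5, 0.0, 0.01]     # loginsindex: intercept, sex, age
theta: 0.02                # loginsindex per kg of weight (the target)
omega: 1.0                 # heteroscedasticity exponent for loginsindex errors
eta: 1.0                   # sex-1 error-scale multiplier (2 when heteroscedastic)
sigma_w: 8.0               # weight error SD (kg)
sigma_l: 0.3               # loginsindex error SD
lognormal_sigma: 0.25      # shape of the standardised log-normal errors
n: 1000                    # observations per simulated dataset
missing_prob: 0.6          # P(weight missing) (restricted to men when subgroup)
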