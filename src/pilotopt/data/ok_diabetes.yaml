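# OK-Diabetes worked example: external pilot + definitive trial programme
# for supported self-management in adults with learning disabilities and
# type II diabetes.  Endpoint: % change in HbA1c at 6 months, SD 1.5;
# target difference 0.5 (benefit coded as positive mu).
scenario:
  endpoint:
    sigma: 1.5
  prior:
    kind: univariate
    m: 0.0
    s: 0.6
  utility:
    d_bar: 0.005
    d_hat: 0.3
    n_star: 50
    rho: 2.0
  mu_star: 0.5
constraints:
  n1_min: 30   # feasibility objectives need at least 30 per arm
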