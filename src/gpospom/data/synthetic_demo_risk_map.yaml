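# SYNTHETIC demo risk map: logistic score -> in-hospital mortality link used
# by the demo pipeline and the statistical simulator.  The coefficients are
# anchored to published per-score observed mortality in a large German
# surgical cohort (~0.3% at 10 points, ~18% at 40 points); they are a
# plausible link for demonstrations, not a published prediction equation.
mode: logistic
logistic:
  intercept: -7.2
  slope: 0.143
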