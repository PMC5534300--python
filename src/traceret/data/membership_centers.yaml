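# Gaussian membership-function centres (mg/l) for the six trace elements,
# per measurement compartment.  "low" and "high" are the centres of the two
# linguistic levels; each pair marks the lower/upper quartile boundary of
# the underlying field-measurement series.
schema_version: 1
centers:
  water:
    Zn: {low: 0.016, high: 0.022}
    Cr: {low: 0.0012, high: 0.0045}
    Fe: {low: 0.0735, high: 0.1}
    Sr: {low: 0.107, high: 0.17775}
    Cu: {low: 0.0012, high: 0.0018}
    Pb: {low: 0.012, high: 0.0165}
  serum:
    Zn: {low: 0.6355, high: 0.8275}
    Cr: {low: 0.04, high: 0.08525}
    Fe: {low: 1.1375, high: 1.9635}
    Sr: {low: 0.08925, high: 0.156}
    Cu: {low: 0.715, high: 0.99275}
    Pb: {low: 0.0475, high: 0.079}
  urine:
    Zn: {low: 0.239, high: 0.4895}
    Cr: {low: 0.012, high: 0.028}
    Fe: {low: 0.0745, high: 0.2195}
    Sr: {low: 0.087, high: 0.222}
    Cu: {low: 0.022, high: 0.084}
    Pb: {low: 0.028, high: 0.055}
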