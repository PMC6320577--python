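# Default CSF reference values (Coimbra laboratory set, Innotest ELISA).
# Reference values are laboratory- and platform-specific; replace them with
# your own centre's cutoffs before scoring real data.
abeta42:
  cutoff: 580.0        # pg/ml, pathologic when decreased
  direction: low
  border_fraction: 0.10
abeta42_40_ratio:
  cutoff: 0.068        # dimensionless, pathologic when decreased
  direction: low
  border_fraction: 0.10
tau:
  cutoff: 250.0        # pg/ml, pathologic when increased
  direction: high
  border_fraction: 0.10
ptau181:
  cutoff: 37.0         # pg/ml, pathologic when increased
  direction: high
  border_fraction: 0.10
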