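# Schema stub for an externally published parameter table.  The layout is
# identical to default.yaml; fill in every pair entry (and the bonded and
# gas sections) from the published table, then remove the 'incomplete'
# flag.  Loading the stub as-is is a hard error.
incomplete: true
meta:
  name: si
units:
  R_c: 0.646
  rho_W: 3.0
  T_DPD: 0.65
  T_real: 293.0
pairs: {}
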