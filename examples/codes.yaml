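# Diagnostic and drug code sets for SUD client case finding.
# Diagnostic codes match by prefix; OAT drug codes match exactly.
sud_diagnostic_codes:
  - "304"
  - "305"
  - F10
  - F11
  - F12
  - F13
  - F14
  - F15
  - F16
  - F18
  - F19
oat_drug_codes:
  - METHADONE
  - BUP-NX
  - SLOW-METHADONE
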