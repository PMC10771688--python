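# Case-finding keyword configuration. Patterns match case-insensitively as
# substrings of the directions-for-use text; the specific tier must be a
# subset of the sensitive tier. Replace with your jurisdiction's lexicon.
sensitive:
  patterns:
    - risk mitigation
    - rmg
    - safer supply
    - safe supply
    - pandemic
    - covid
    - witnessed daily
  med_classes: [opioid, stimulant, benzodiazepine]
specific:
  patterns:
    - risk mitigation
    - rmg
    - safer supply
  med_classes: [opioid, stimulant, benzodiazepine]
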