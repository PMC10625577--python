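# Occupation scheme: three digits plus a letter (e.g. "211A").
# Digits define levels 1-3; the letter completes level 4.
name: PCS2003
placeholder: "#"
alphabet:
  - "0123456789"
  - "0123456789"
  - "0123456789"
  - "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
separators: []
levels:
  - 1
  - 2
  - 3
  - 4
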