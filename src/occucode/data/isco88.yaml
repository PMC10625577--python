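# Occupation scheme: four digits (e.g. "2221"); major, sub-major, minor and
# unit groups are prefixes of 1-4 digits.
name: ISCO88
placeholder: "#"
alphabet:
  - "0123456789"
  - "0123456789"
  - "0123456789"
  - "0123456789"
separators: []
levels:
  - 1
  - 2
  - 3
  - 4
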