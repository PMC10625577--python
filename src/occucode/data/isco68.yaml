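# Occupation scheme: five digits rendered with "-" after the first and "."
# after the third (e.g. "1-21.10"). Major, minor, unit and occupation levels
# are prefixes of 1, 2, 3 and 5 digits. Shorter raw codes (e.g. "1-21") are
# right-padded with placeholders.
name: ISCO68
placeholder: "#"
alphabet:
  - "0123456789"
  - "0123456789"
  - "0123456789"
  - "0123456789"
  - "0123456789"
separators:
  - [1, "-"]
  - [3, "."]
levels:
  - 1
  - 2
  - 3
  - 5
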