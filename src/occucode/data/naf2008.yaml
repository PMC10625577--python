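# Activity-sector scheme: four digits plus a letter (e.g. "4231A").
# Level 1 is the section (21 categories), looked up from the 2-digit division;
# levels 2-5 are prefixes of 2, 3, 4 and 5 significant characters.
name: NAF2008
placeholder: "#"
alphabet:
  - "0123456789"
  - "0123456789"
  - "0123456789"
  - "0123456789"
  - "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
separators: []
levels:
  - depth: 2
    table:
        "01": A
        "02": A
        "03": A
        "05": B
        "06": B
        "07": B
        "08": B
        "09": B
        "10": C
        "11": C
        "12": C
        "13": C
        "14": C
        "15": C
        "16": C
        "17": C
        "18": C
        "19": C
        "20": C
        "21": C
        "22": C
        "23": C
        "24": C
        "25": C
        "26": C
        "27": C
        "28": C
        "29": C
        "30": C
        "31": C
        "32": C
        "33": C
        "35": D
        "36": E
        "37": E
        "38": E
        "39": E
        "41": F
        "42": F
        "43": F
        "45": G
        "46": G
        "47": G
        "49": H
        "50": H
        "51": H
        "52": H
        "53": H
        "55": I
        "56": I
        "58": J
        "59": J
        "60": J
        "61": J
        "62": J
        "63": J
        "64": K
        "65": K
        "66": K
        "68": L
        "69": M
        "70": M
        "71": M
        "72": M
        "73": M
        "74": M
        "75": M
        "77": N
        "78": N
        "79": N
        "80": N
        "81": N
        "82": N
        "84": O
        "85": P
        "86": Q
        "87": Q
        "88": Q
        "90": R
        "91": R
        "92": R
        "93": R
        "94": S
        "95": S
        "96": S
        "97": T
        "98": T
        "99": U
  - 2
  - 3
  - 4
  - 5
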