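{
  "pap": [
    "pap smear",
    "pap test",
    "pap smeer",
    "papsmear",
    "pap-smear"
  ],
  "cervical cancer": [
    "cervical cancer",
    "cervical cancar",
    "cervicle cancer"
  ]
}
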