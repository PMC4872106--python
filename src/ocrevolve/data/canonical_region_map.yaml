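scaffold:
  name: synthetic_ocr_scaffold
  length: 116
  chargeable:
  - 4
  - 8
  - 12
  - 16
  - 20
  - 24
  - 28
  - 32
  - 36
  - 40
  - 44
  - 48
  - 52
  - 56
  - 60
  - 63
  - 66
  - 69
  - 72
  - 75
  - 78
  - 81
  - 84
  - 88
  - 92
  - 95
  - 98
  - 101
  - 104
  - 107
  - 109
  - 111
  - 113
  - 115
regions:
  central:
  - 56
  - 60
  - 63
  - 66
  - 69
  - 72
  - 75
  - 78
  - 81
  specific:
  - 32
  - 36
  - 40
  - 44
  - 48
  - 52
  - 84
  - 88
  - 92
  - 95
  flanking:
  - 4
  - 8
  - 12
  - 16
  - 20
  - 24
  - 28
  - 98
  - 101
  - 104
  - 107
  - 109
  - 111
  - 113
  - 115
  loop1:
  - 36
  - 40
  - 44
  - 48
  - 52
  loop2:
  - 60
  - 63
  - 66
  - 69
  - 72
  - 75
  - 78
position88: 88
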