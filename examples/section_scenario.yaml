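# Section-preparation study conditions: three spicule clusters
seed: 123
prep: section
clusters:
- name: SC I
  parts:
  - C
  - O
  - Ca
  - Mg
  - Traces
  center:
  - 20.07
  - 46.05
  - 19.8
  - 1.6
  - 12.48
  total_variance: 0.1063
  n: 14
- name: SC II
  parts:
  - C
  - O
  - Ca
  - Mg
  - Traces
  center:
  - 9.47
  - 61.96
  - 21.72
  - 3.94
  - 2.9
  total_variance: 0.2553
  n: 41
- name: SC III
  parts:
  - C
  - O
  - Ca
  - Mg
  - Traces
  center:
  - 8.06
  - 53.49
  - 33.82
  - 2.88
  - 1.74
  total_variance: 0.2567
  n: 45
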