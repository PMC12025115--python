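# Fracture-preparation study conditions: four higher-variance clusters
seed: 456
prep: fracture
clusters:
- name: FC I
  parts:
  - C
  - O
  - Ca
  - Mg
  - Traces
  center:
  - 14.79
  - 29.69
  - 36.53
  - 1.26
  - 17.72
  total_variance: 0.7958
  n: 19
- name: FC II
  parts:
  - C
  - O
  - Ca
  - Mg
  - Traces
  center:
  - 11.58
  - 53.55
  - 29.59
  - 3.2
  - 2.07
  total_variance: 0.708
  n: 27
- name: FC III
  parts:
  - C
  - O
  - Ca
  - Mg
  - Traces
  center:
  - 10.46
  - 62.46
  - 16.75
  - 5.32
  - 5.0
  total_variance: 0.3288
  n: 19
- name: FC IV
  parts:
  - C
  - O
  - Ca
  - Mg
  - Traces
  center:
  - 17.31
  - 53.32
  - 15.91
  - 1.91
  - 11.54
  total_variance: 0.992
  n: 40
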