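name: fig7_worstcase_Z40
analyte: [benzene, toluene, acetone, dichloromethane]
coating: car_pdms
device:
  kind: needle_23ga
  Z: 40 mm
program:
  breakpoints:
    - [0 s, 1.176 umol/m3]
    - [49000 s, 1.176 umol/m3]
    - [51000 s, 0.1176 umol/m3]
    - [100000 s, 0.1176 umol/m3]
t_end: 100000 s
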