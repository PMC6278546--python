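name: fig6_Z40
analyte: [benzene, toluene, acetone, dichloromethane]
coating: car_pdms
device:
  kind: needle_23ga
  Z: 40 mm
program:
  constant: 0.641 umol/m3
t_end: 100000 s
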