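name: fig4_benzene
analyte: benzene
coating: car_pdms
device:
  kind: needle_24ga
  Z: 10 mm
program:
  constant: 0.641 umol/m3
t_end: 100000 s
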