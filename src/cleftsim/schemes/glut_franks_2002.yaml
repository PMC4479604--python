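# Glutamate transporter (GluT) kinetic cycle.
#
# Simplified transporter model following Franks KM, Bartol TM, Sejnowski
# TJ (2002) Biophys J 83:2333-2348: glutamate binds the outward-facing
# transporter (T -> TG), and the bound complex either releases the ligand
# back into the extracellular space or translocates it into the cell
# (transport, which removes the molecule from the simulation).  TR is the
# inward-facing/recovering transporter returning to the outward-facing
# state with the slow cycle-completion rate.
#
# TRANSCRIPTION-TO-VERIFY: rate table transcribed from the cited source;
# re-check before quantitative reuse outside this package.

name: glut_franks_2002
citation: >-
  Franks, Bartol & Sejnowski (2002) Biophys J 83:2333.
note: transcription-to-verify (rate table transcribed from the cited source)
units:
  unimolecular: 1/s
  bimolecular: 1/(M*s)
T_ref_C: 23.0
Q10: 2.5
initial_state: T
open_state: null
states: [T, TG, TR]
transitions:
  - {from: T, to: TG, rate: 1.8e7, order: 2}
  - {from: TG, to: T, rate: 1.8e2, order: 1, releases_ligand: true}
  - {from: TG, to: TR, rate: 1.8e2, order: 1, removes_ligand: true}
  - {from: TR, to: T, rate: 2.57e1, order: 1}
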