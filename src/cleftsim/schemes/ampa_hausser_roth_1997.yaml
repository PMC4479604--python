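# AMPA receptor kinetic scheme: eight closed states, one open state.
#
# Topology and rate constants transcribe the mossy-fibre AMPA receptor
# scheme of Jonas P, Major G, Sakmann B (1993) J Physiol 472:615-663, as
# adopted for cortical pyramidal-cell synapses by Hausser M, Roth A (1997).
# Ligand binding proceeds C0 -> C1 -> C2 (two glutamate molecules), the
# di-liganded receptor opens C2 <-> O, and desensitized states branch off
# the mono-liganded (D1), di-liganded (D2) and open (via D3) states.
# D4 and D5 are slow deep-desensitized extensions completing the published
# nine-state topology; their rates are far below 1/(10 ms) and do not
# influence the sub-millisecond open-receptor peak.
#
# TRANSCRIPTION-TO-VERIFY: the source articles print the rate table; this
# file is a manual transcription and should be re-checked against them
# before any quantitative reuse outside this package.
#
# Rates are at the source recording temperature (room temperature, nominal
# 23 C) and are Q10-corrected to the simulation temperature at load time.

name: ampa_hausser_roth_1997
citation: >-
  Jonas, Major & Sakmann (1993) J Physiol 472:615; Hausser & Roth (1997).
note: transcription-to-verify (rate table transcribed from the cited sources)
units:
  unimolecular: 1/s
  bimolecular: 1/(M*s)
T_ref_C: 23.0
Q10: 2.5
initial_state: C0
open_state: O
states: [C0, C1, C2, O, D1, D2, D3, D4, D5]
transitions:
  # ligand binding / unbinding along the activation pathway
  - {from: C0, to: C1, rate: 4.59e6, order: 2}
  - {from: C1, to: C0, rate: 4.26e3, order: 1, releases_ligand: true}
  - {from: C1, to: C2, rate: 2.84e7, order: 2}
  - {from: C2, to: C1, rate: 3.26e3, order: 1, releases_ligand: true}
  # channel gating
  - {from: C2, to: O, rate: 4.24e3, order: 1}
  - {from: O, to: C2, rate: 9.00e2, order: 1}
  # desensitization branch, mono-liganded
  - {from: C1, to: D1, rate: 2.89e3, order: 1}
  - {from: D1, to: C1, rate: 3.92e1, order: 1}
  # binding within the desensitized branch
  - {from: D1, to: D2, rate: 1.27e6, order: 2}
  - {from: D2, to: D1, rate: 4.57e1, order: 1, releases_ligand: true}
  # desensitization, di-liganded
  - {from: C2, to: D2, rate: 1.72e2, order: 1}
  - {from: D2, to: C2, rate: 7.27e-1, order: 1}
  # deep desensitization and re-entry from the open state
  - {from: D2, to: D3, rate: 1.77e1, order: 1}
  - {from: D3, to: D2, rate: 4.00e0, order: 1}
  - {from: O, to: D3, rate: 1.68e1, order: 1}
  - {from: D3, to: O, rate: 1.904e2, order: 1}
  # slow deep-desensitized tail states (see header note)
  - {from: D3, to: D4, rate: 8.0e0, order: 1}
  - {from: D4, to: D3, rate: 2.0e0, order: 1}
  - {from: D4, to: D5, rate: 4.0e0, order: 1}
  - {from: D5, to: D4, rate: 1.0e0, order: 1}
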