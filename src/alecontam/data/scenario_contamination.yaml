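# Contamination-after-T5 scenario: 5% of culture B is mixed into cultures A
# and C at the first transfer after the T5 sampling point (generation ~153).
# The donor-derived fabF+marC+yghB lineage then acquires rob_3 (and frmR_1
# in A) within the recipients, so A and C no longer assemble that genotype
# from their own late introductions; their other events match the reference
# scenario.  The donor lineage carries per-recipient per-mutation fitness
# offsets (lineage_fitness) which, together with the proportion of the
# post-contamination introductions (label "post"), are the ten parameters
# freed in the fitted contamination model on top of the reference ten.
mutations: [fabF_1, marC_3, P_yghB, marC_1, rob_1, rob_2, rob_3, frmR_1, frmR_2]
selection:
  fabF_1: 0.032
  marC_3: 0.147
  P_yghB: 0.074
  marC_1: 0.888
  rob_1: 0.748
  rob_2: 0.465
  rob_3: 1.502
  frmR_1: 0.522
  frmR_2: 1.000
cultures: [A, B, C]
pi: 0.053
introductions:
  - {mutation: fabF_1, culture: A, generation: 32, background: [], label: A_fabF}
  - {mutation: marC_3, culture: A, generation: 62, background: [fabF_1], label: A_marC}
  - {mutation: marC_1, culture: A, generation: 108, background: [], label: A_marC1}
  - {mutation: rob_3, culture: A, generation: 155, background: [fabF_1, marC_3, P_yghB],
     pi: 0.005, label: post}
  - {mutation: frmR_1, culture: A, generation: 177,
     background: [fabF_1, marC_3, P_yghB, rob_3], pi: 0.005, label: post}
  - {mutation: fabF_1, culture: B, generation: 32, background: [], label: B_fabF}
  - {mutation: marC_3, culture: B, generation: 62, background: [fabF_1], label: B_marC}
  - {mutation: P_yghB, culture: B, generation: 108, background: [fabF_1, marC_3], label: B_yghB}
  - {mutation: rob_2, culture: B, generation: 149, background: [fabF_1, marC_3, P_yghB], label: B_rob2}
  - {mutation: frmR_2, culture: B, generation: 177,
     background: [fabF_1, marC_3, P_yghB, rob_2], label: B_frmR2}
  - {mutation: P_yghB, culture: C, generation: 108, background: [], label: C_yghB}
  - {mutation: rob_1, culture: C, generation: 126, background: [], label: C_rob1}
  - {mutation: rob_3, culture: C, generation: 155, background: [fabF_1, marC_3, P_yghB],
     pi: 0.005, label: post}
sampling: [32, 62, 108, 126, 149, 177, 226]
timepoint_labels: [T1, T2, T3, T4, T5, T6, T7]
contamination:
  - {donor: B, recipient: A, after: T5, proportion: 0.05}
  - {donor: B, recipient: C, after: T5, proportion: 0.05}
lineage_fitness:
  A: {fabF_1: 0.0, marC_3: 0.0, P_yghB: 0.0, rob_3: 0.0, frmR_1: 0.0}
  C: {fabF_1: 0.0, marC_3: 0.0, P_yghB: 0.0, rob_3: 0.0}
kappa: 0.0
seed: 0
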