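# No-contamination reference scenario for the three-culture isoprenol ALE.
#
# Nine tracked mutations: the persistent target alleles (fabF_1, marC_3,
# P_yghB, rob_3), the transient rob_1/rob_2 and frmR alleles, and marC_1 as
# the marker of the recurrent culture-A intermediate genotype.  Each mutant
# lineage enters at the sampling point preceding the mutation's first
# observation (P_yghB uniformly at generation 108 in all three cultures,
# rob_3 uniformly one transfer after T5 at generation 155); chained events
# are staggered by one sampling interval so the background lineage exists.
# All events share the scenario-wide introduction proportion pi.
#
# The selection coefficients below are per-doubling growth advantages; they
# are the fitted operating point of the model and serve as the first
# optimiser start when the scenario is refitted.
mutations: [fabF_1, marC_3, P_yghB, marC_1, rob_1, rob_2, rob_3, frmR_1, frmR_2]
selection:
  fabF_1: 0.087
  marC_3: 0.327
  P_yghB: 0.277
  marC_1: 0.895
  rob_1: 0.701
  rob_2: 0.533
  rob_3: 0.907
  frmR_1: 0.368
  frmR_2: 0.366
cultures: [A, B, C]
pi: 0.001
introductions:
  # culture A: early fabF+marC lineage, overtaken by the marC_1-marked
  # intermediate genotype, finally swept by the rob_3 lineage
  - {mutation: fabF_1, culture: A, generation: 32, background: [], label: A_fabF}
  - {mutation: marC_3, culture: A, generation: 62, background: [fabF_1], label: A_marC}
  - {mutation: P_yghB, culture: A, generation: 108, background: [fabF_1, marC_3], label: A_yghB}
  - {mutation: marC_1, culture: A, generation: 108, background: [], label: A_marC1}
  - {mutation: rob_3, culture: A, generation: 155, background: [fabF_1, marC_3, P_yghB],
     label: post}
  - {mutation: frmR_1, culture: A, generation: 177,
     background: [fabF_1, marC_3, P_yghB, rob_3], label: post}
  # culture B: fabF+marC persist from T3; yghB, rob_2 and frmR_2 stack on top
  - {mutation: fabF_1, culture: B, generation: 32, background: [], label: B_fabF}
  - {mutation: marC_3, culture: B, generation: 62, background: [fabF_1], label: B_marC}
  - {mutation: P_yghB, culture: B, generation: 108, background: [fabF_1, marC_3], label: B_yghB}
  - {mutation: rob_2, culture: B, generation: 149, background: [fabF_1, marC_3, P_yghB], label: B_rob2}
  - {mutation: frmR_2, culture: B, generation: 177,
     background: [fabF_1, marC_3, P_yghB, rob_2], label: B_frmR2}
  # culture C: promoter deletion first, transient rob_1, then the full
  # fabF+marC+yghB+rob_3 genotype assembled within the culture
  - {mutation: P_yghB, culture: C, generation: 108, background: [], label: C_yghB}
  - {mutation: rob_1, culture: C, generation: 126, background: [], label: C_rob1}
  - {mutation: fabF_1, culture: C, generation: 126, background: [P_yghB], label: C_fabF}
  - {mutation: marC_3, culture: C, generation: 149, background: [fabF_1, P_yghB], label: C_marC}
  - {mutation: rob_3, culture: C, generation: 155, background: [fabF_1, marC_3, P_yghB],
     label: post}
sampling: [32, 62, 108, 126, 149, 177, 226]
timepoint_labels: [T1, T2, T3, T4, T5, T6, T7]
contamination: []
kappa: 0.0
seed: 0
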