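# alecontam

Analysis toolkit for serial-passage adaptive laboratory evolution (ALE)
resequencing studies, built around one concrete question: when replicate
evolution cultures suddenly converge on near-identical genotypes, did the
same mutations win independently, or did cells leak between flasks?

The motivating dataset is a three-replicate *E. coli* isoprenol-tolerance
evolution sequenced at seven time-points (one clone per culture per point,
21 isolates, 24 catalogued mutations).  After ~177 generations all three
replicates carry the same fabF, marC and yghB-promoter mutations plus one of
two rob alleles — striking convergence that followed a restart from
cryo-stock.  The package provides:

- **catalog / trajectory statistics** — mutation-table and genotype-matrix
  parsing with per-cell provenance, frequency and first-occurrence
  statistics, persistent target genes, shared exact mutations,
  complete-linkage genotype clustering, and an inverted-repeat finder for
  promoter motifs;
- **a serial-passage simulator** — genotype frequencies under additive
  per-doubling selection `w(g) = 1 + Σ s_m`, dilution bottlenecks
  (deterministic or multinomial), timed introduction of mutant lineages at
  proportion Pi, clone sampling, and cross-contamination mixing
  `recipient ← (1−c)·recipient + c·donor`;
- **contamination inference** — the clone-sampling log-likelihood
  `Σ ln f(observed genotype)`, bounded multi-start maximum-likelihood
  fitting, likelihood-ratio tests (`LR = 2Δℓ` against χ²_df), a
  contamination-timing scan and profile-likelihood sensitivity analyses;
- **fitness metrics** — growth rate by log-linear OD fit (1/h), relative
  fitness, IC50 by interpolation or Hill fit `μ0/(1+(c/IC50)^h)`, and the
  additive expectation `1 + Σ(w_i − 1)` for combined mutations;
- **seeded synthetic-data generators** for all of the above, plus the
  packaged study fixture (catalog, reconstructed 21-isolate genotype
  matrix, observation series, and the study-reproduction scenario pair).

## Worked example

```python
from alecontam import fixture
from alecontam.inference import fit_model, likelihood_ratio_test

records, matrix, obs, (ref_cfg, con_cfg) = fixture.packaged_fixture()

f0 = fit_model(obs, ref_cfg, fixture.reference_free_params(), seed=1)
f1 = fit_model(obs, con_cfg, fixture.contamination_free_params(), seed=1)
lrt = likelihood_ratio_test(f0.loglik, f1.loglik, f1.k - f0.k)
print(round(f0.loglik, 2), round(f1.loglik, 2),
      lrt.df, round(lrt.p_value, 2))
```

prints

```
-5.58 -2.96 10 0.87
```

The no-contamination model explains the 21 observed clone genotypes with a
maximised log-likelihood of −5.58; assuming 5% cross-contamination from
culture B into A and C after the fifth sampling point raises it to −2.96.
The improvement (LR = 5.24 at df = 10, p = 0.87) is far from significant at
α = 0.05: the observed convergence does not require the contamination
hypothesis.  The same conclusion end-to-end, including the timing scan that
ranks contamination-after-T5 above every other timing:

```
alecontam reproduce-study --out results/
```

which also reports the 4 persistent target genes (fabF, marC, the yghB
promoter, rob) and the 3 exact mutations shared by all final isolates.

Other entry points: `alecontam catalog stats`, `alecontam catalog cluster`,
`alecontam motif --k 9 <sequence>`, `alecontam simulate`, `alecontam fit`,
`alecontam scan-contamination`, `alecontam fitness rate|ic50|relative`,
`alecontam generate growth|dose|ale`, `alecontam validate`.  Every command
honours `--seed` and writes a run manifest next to its outputs.

See `docs/methods.md` for the model, its assumptions, the parameter
accounting behind the df = 10 comparison, and known limitations.

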