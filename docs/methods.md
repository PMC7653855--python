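# Methods

## The problem

In a serial-passage adaptive laboratory evolution (ALE) experiment, three
replicate *E. coli* cultures were propagated under isoprenol stress for about
226 generations, and a single clone per culture was isolated and resequenced
at seven time-points (after roughly 32, 62, 108, 126, 149, 177 and 226
generations).  Around the sixth time-point the three replicates converge on
nearly identical genotypes — the same fabF, marC and yghB-promoter mutations,
plus one of two rob alleles.  Because only one clone per point was sequenced,
two explanations are possible: parallel evolution with clone-sampling
coincidence, or cross-contamination between replicate flasks (which had been
restarted from cryo-stock shortly before the convergence).  The package
implements the machinery to weigh these hypotheses quantitatively, plus the
descriptive trajectory statistics and growth-based fitness metrics that
surround the question.

## Serial-passage model

A culture is a set of genotypes `g` (subsets of tracked mutations) with
relative abundances.  Fitness is additive on the per-doubling scale:

    w(g) = 1 + sum_{m in g} s_m

During a growth phase of `d` doublings, abundance multiplies by
`2^(d * w(g))`; the deterministic trajectory therefore has the closed form of
competing exponentials and, for a single mutant introduced at proportion
`pi`, reduces to the logistic

    f(t) = pi 2^(s t) / (pi 2^(s t) + 1 - pi).

Transfers dilute the culture 1:100 (6.64 doublings per batch).  In
deterministic mode a transfer only rescales abundances; in stochastic mode
the founding population of the next batch is a multinomial draw of `N_b`
cells (default `N_b = 10^6`).  Mutations do not arise spontaneously: each
tracked mutant lineage is introduced by a configured event at proportion
`pi` carved from an explicit background genotype, which must itself be
segregating above `pi` at that moment (otherwise the scenario is
infeasible).  Cross-contamination is frequency mixing,
`recipient <- (1-c) recipient + c donor`, applied at the first transfer after
the configured sampling point; donor-derived genotypes are tagged so the
model can give the imported lineage its own per-mutation fitness offsets in
the recipient.  Abundances are relative throughout; only frequencies are
interpreted, and the growth update is renormalised against the fittest
genotype so that long horizons cannot overflow.

Clone isolation is modelled as drawing one genotype with probability
proportional to `frequency * w(g)^kappa`; `kappa = 0` (unbiased) is the
default.  The experiment picked large, fast-growing colonies, which would
correspond to `kappa > 0`; the parameter is exposed but not used in the
shipped analyses because nothing in the observed series identifies it.

## Observation likelihood and fitting

With one sequenced clone per culture and time-point, the likelihood of an
observation is simply the modelled frequency of the observed genotype
(mutation sets are compared after projection onto the tracked mutations, and
lineage tags are ignored).  The total log-likelihood is

    l = sum_obs ln max(f_obs, eps),     eps = 1e-6,

where the floor keeps impossible observations finite without dominating
fits; on the packaged fixture no observation is at the floor at either MLE
(tested).  Likelihoods always use the deterministic expectation — with 21
observations there is no hope of identifying drift, so the stochastic
simulator is reserved for data generation.

Fits are bounded multi-start local optimisation: L-BFGS-B on the natural
scale for selection coefficients (bounds (-0.5, 2)) and offsets, and on
log10 scale for proportions (`pi` in (1e-6, 0.5), `c` in (0, 0.5)), followed
by a Nelder-Mead polish.  The first start is the template's own parameter
values; half the remaining starts jitter that point and half sample the
bounds uniformly, because the surface is rugged: wherever a background
lineage dies out before its introduction event the scenario is infeasible
and the objective is a penalty plateau.  Default 20 starts; the seed is
recorded, and results are deterministic given the seed (float accumulation
uses a canonical mutation order, so hash randomisation cannot perturb the
optimiser's path).

## The shipped scenario pair and the df = 10 comparison

The reconstruction tracks nine mutations: the four persistent target alleles
(fabF_1, marC_3, P_yghB, rob_3), the transient rob_1/rob_2 and frmR_1/frmR_2
alleles, and marC_1 as the marker of the recurrent culture-A intermediate
genotype (in reality a four-mutation genotype; a single marker suffices
because its companions never appear separately).  Introduction times are
fixed by rule, not fitted: each lineage enters at the sampling point
preceding the mutation's first observation anywhere in the experiment, with
chained events staggered by one interval so their background exists, and
two mutations entering uniformly in all relevant cultures (the yghB promoter
deletion at generation 108; rob_3 one transfer after T5, at generation 155).
All events share a single global `pi`.

*Reference (no contamination) model* — free parameters: the nine selection
coefficients and `pi` (k = 10).  Culture C must assemble
fabF+marC+yghB+rob_3 through its own chain of late introductions, and
culture A's rob_3 background (its own fabF+marC+yghB lineage) must survive
under the dominance of the marC_1 genotype; both requirements fight the
same shared coefficients that must also keep culture B's yghB lineage
subdominant at T5 and fit the T4 observations.  These tensions, not any
single observation, produce the residual misfit of the fitted reference
model.

*Contamination model* — same tracked mutations and early events, but 5% of
culture B is mixed into A and C at the first transfer after T5, the
recipients' own late chains are removed, and rob_3/frmR_1 arise on the
imported lineage.  Free parameters: the reference ten plus ten
contamination-specific ones — per-recipient, per-mutation fitness offsets of
the donor-derived lineage (five in A, four in C; the cultures were restarted
from cryo-stock and stress levels differed, so the imported lineage need
not grow at donor rates) and the shared proportion of the
post-contamination introductions.  The mixing proportion itself stays
pinned at the assumed 5%.  The likelihood-ratio test therefore has
df = 20 - 10 = 10.  The parameter accounting is a modelling choice made
explicit in the two shipped YAML files and editable there.

The timing scan refits the contamination model with the mixing point moved
across T1..T6 and the proportion across {0.01, 0.05, 0.1}.  For early mixing
points the donor cannot yet deliver the fabF+marC+yghB lineage; the scan
then falls back to a structure where the recipients keep their own chains
and the donor only admixes.  Scenarios for which no feasible
parameterisation exists at all (very early mixing destroys the backgrounds
culture C's own trajectory requires) are reported with log-likelihood
negative infinity and rank last.  Adding free parameters never decreases
the maximised log-likelihood along a nested pair (tested).

## Fixture reconstruction

The per-isolate genotype matrix is not published as a table; the packaged
21-isolate x 24-mutation matrix is reconstructed from the catalog's
frequency column plus the explicit statements about persistence,
convergence and the repeated culture-A genotype.  With 21 isolates every
printed percentage is a unique carrier count (5% -> 1, 10% -> 2, 19% -> 4,
33% -> 7, 48% -> 10), which pins the reconstruction tightly; cells that are
implied by counts rather than stated directly (for example which culture
carries the tenth fabF_1/marC_3 isolate at T3, or the seventh yghB-promoter
carrier at T4) are flagged `i` in the companion provenance file, stated
cells `s`.  Frequencies are rounded half away from zero (10/21 -> 48).
Allelic variants group to one gene target, so the four persistent targets
are fabF, marC, the yghB promoter region and rob even though rob has three
distinct alleles.

## Trajectory statistics, clustering, motifs

Mutation frequency, first occurrence, persistent target genes and
shared-exact-mutation sets are direct functions of the matrix.  Genotype
clustering is complete-linkage (farthest-neighbour) agglomeration on plain
Euclidean distance between 0/1 vectors, written out directly (O(n^3),
trivial at n = 21) so that ties break deterministically toward the lowest
original row index; scipy's implementation serves as an independent oracle
in tests on tie-free data, and an exhaustive re-agglomeration oracle covers
small binary matrices.  The inverted-repeat finder reports all 0-based
position pairs `(i, j)` where the reverse complement of the k-mer at `i`
occurs at `j > i` within a gap limit (1-based in CLI reports); it is checked
against an O(n^2) brute force and against planted motif/inverted-copy pairs
in random sequence.

## Fitness metrics

Growth rate is the OLS slope of ln(OD600) against time, units 1/h; the
automatic window is the contiguous span of at least four points maximising
R^2 (ties prefer longer, then earlier, windows), since saturating readings
otherwise bias the slope.  Relative fitness is the ratio to the parental
strain's rate under identical conditions.  IC50 comes either from linear
interpolation between the concentrations bracketing half the unstressed
rate (the default, matching how a dashed line is read off a dose-response
plot) or from a least-squares Hill fit `mu0 / (1 + (c/IC50)^h)` with h > 0
unconstrained.  The additive expectation for combined mutations is
`1 + sum (w_i - 1)`.

## Synthetic data

Growth curves carry multiplicative log-normal noise on OD (`OD(t) = od0
e^{mu t} e^{eta}`, `eta ~ N(0, cv^2)`) — plate/flask error scales with
signal; dose-response rates carry additive Gaussian noise truncated at zero,
mirroring replicate SD of rate estimates.  ALE datasets run the stochastic
simulator and sample one clone per culture and sampling generation.  The
recovery scenario used in calibration introduces a single `s = 0.15` mutant
at `Pi = 0.01` at staggered generations (0, 20, 40) in the three cultures at
the study's sampling generations — staggering makes replicates differ, so
cross-contamination is in principle detectable.  All generators are
bit-reproducible given a seed.

Selection-coefficient recovery is assessed with `Pi` held at its design
value.  With one clone per point, `s` and `Pi` are jointly unidentifiable:
any sufficiently sharp sweep (large `s`, tiny `Pi`) that crosses between
the same two sampling points fits binary clone series perfectly, so the
joint MLE drifts toward the sharp-sweep ridge.  Fixing `Pi` restores
identifiability; the median recovery error at the study's design is then
about 0.02-0.04 (tested at 20 replicate datasets).

## Numerical choices

- Frequency floor `eps = 1e-6`; doubling or halving it changes nothing on
  the fixture fits (tested).
- Chi-square upper tail via the regularised incomplete gamma
  `Q(df/2, x/2)`; agrees with the closed-form even-df series to 1e-12.
- Deterministic runs are seed-independent; stochastic runs use one named
  RNG stream per culture derived from the scenario seed, so cultures are
  independently reproducible.
- Clustering and introduction-event ties break toward the lowest index /
  the highest-abundance background copy.
- Problem sizes in the shipped calibrations: 20 datasets for recovery, 50
  for the null scan, 500 replicates for stochastic-deterministic
  convergence, 8 optimiser starts for the one-parameter synthetic fits and
  20 for the scenario-pair fits.

## What passing tests do and do not show

The synthetic generators emulate clone-sampling noise, bottleneck drift and
measurement error, but not: de-novo mutation supply (lineages appear only
by configured events), concentration-dependent fitness under the rising
isoprenol schedule, epistasis (fitness is additive unless overridden
per-genotype), lag/death phases or resource competition, or colony-size
bias in clone isolation.  Agreement of the fitted scenario pair with the
reported log-likelihoods shows that a model of this family reproduces the
published comparison under the documented parameter accounting, not that it
is the authors' exact model, whose full specification is not public.  The
non-significant LRT is a statement about power at 21 observations, not
evidence that contamination was absent.
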