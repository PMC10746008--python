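# Methods

`ecotyping` implements the computational workflow used to delimit closely
related bacterial populations ("ecotypes" or, when the distinction is purely
geographic, "geotypes") from libraries of 16S rRNA gene fragments, together
with the ancillary screens that such a study needs: in-silico PCR and RFLP
typing of candidate sequences, fragment-based average nucleotide identity
(ANI) between genomes, and a permutation test of whether demarcated clades
track environmental parameters. This note records the models, the parameter
choices and their rationale, and the known limits of what the synthetic
experiments demonstrate.

## Distances and binning curves

All sequence comparison starts from the proportion of differing positions
(p-distance) under **pairwise deletion**: a column is compared only when both
sequences carry an unambiguous A/C/G/T. The Jukes–Cantor correction
`d = -(3/4) ln(1 - (4/3) p)` maps p to expected substitutions per site; it is
the canonical one-parameter correction, monotone in p, so every ordering
statement made on corrected distances holds on observed ones as well. A
`strict` policy that refuses gaps and ambiguity codes is available for
curated alignments.

A **binning curve** summarises an alignment as the number of sequence
clusters at each identity criterion, using complete-linkage clustering: a
bin at criterion c is a maximal set whose pairwise identities are all ≥ c.
At criterion 1.0 the count equals the number of distinct sequences; it
decays monotonically to 1 as the criterion is relaxed. Complete linkage (via
`scipy.cluster.hierarchy`) is the strict reading of "all members at least
c identical"; single linkage is available behind a flag for sensitivity
analysis. Two criteria grids ship as defaults:

* `DEFAULT_CRITERIA` — {1.000, 0.995, 0.99, 0.98, 0.97, 0.96, 0.95, 0.90,
  0.85, 0.80}, bracketing the 0–5% divergence range of closely related
  libraries; used for reporting and for the global model fit.
* `FINE_CRITERIA` — adds 0.999…0.996 in 0.1% steps; used by the recursive
  demarcation, because the coarse grid has no resolution in the 1–3 nt
  "microheterogeneity" range that separates clonal variation from genuinely
  distinct populations.

## The Stable Ecotype Model simulator

The model assumes a lineage diversifies through occasional **ecotype
formation** events and recurrent **periodic selection** events, each sweep
purging the diversity of one ecotype. Three quantities are estimated:

| parameter | meaning | units |
|---|---|---|
| `omega` | net ecotype-formation rate | events / ecotype / (subs/site) |
| `sigma` | periodic-selection rate | events / ecotype / (subs/site) |
| `npop`  | number of ecotype (geotype) populations | integer ≥ 1 |

Simulation runs backward in time with exponential waiting times. n sampled
lineages are assigned to `npop` ecotypes (uniformly, conditioned on no
ecotype being empty); each ecotype with ≥ 2 surviving lineages experiences a
sweep at rate `sigma` (all its lineages coalesce), and each ecotype merges
into another at rate `omega` while at least two remain. At a total backward
`depth` the survivors join at the root. A root sequence of length L then
evolves down the genealogy under Jukes–Cantor with per-branch substitution
probability `p(b) = (3/4)(1 − e^(−4b/3))`. The implementation is exactly
this per-site model but is executed sparsely — per-branch Binomial(L, p(b))
mutation counts, distinct positions, and additive base shifts mod 4 — so a
replicate touches only mutated columns (~0.5 ms at n = 40, L = 750).

The **likelihood** of a parameter triple is the fraction of R replicates
whose binning curve matches the observed one at every criterion, within a
multiplicative tolerance band (default 1.1) whose endpoints are rounded to
the **nearest** integer. Nearest rounding keeps a 10% band meaning 10%:
counts below 5 must match exactly, a count of 20 may be off by 2. (Rounding
the band outward instead makes ±10% equal to ±1 bin at every realistic
count, and the ecotype number becomes unidentifiable — the measured ML count
wandered between npop−1 and npop+1 on 4-ecotype data.) Replicate i draws
from a substream seeded by (seed, i), so raising R extends rather than
reshuffles the replicate set, and every estimate is bit-reproducible.

**Simulation depth.** The time to root is estimated as half the *median*
off-diagonal corrected distance. In a sample containing several diverged
populations most pairs sit at the deepest split, so the median estimates
twice the root depth; the maximum (the naive choice) is an extreme order
statistic over hundreds of binomially noisy pairs and overshot the true
depth by ~35% at L = 750, visibly shifting where simulated curves merge.
Inside the demarcation recursion the per-clade depth is half the clade's
*maximum* corrected divergence — there the question is whether the clade's
deepest split is a population boundary, and that split is exactly where a
multi-population hypothesis would place its root.

## Fitting and confidence intervals

`fit_parameters` maximises the match fraction over (log₁₀ omega, log₁₀
sigma, log₁₀ npop) with Nelder–Mead, rounding npop to an integer inside
every evaluation and using a fixed replicate seed per restart (common random
numbers) so the objective is deterministic in the parameters. Because the
match-fraction surface is a zero plateau almost everywhere, the simplex is
seeded by a coarse lattice scan (10 sigma decades-spaced values × 2 omega
values × ~10 candidate npop values, at R/4 replicates); Nelder–Mead then
refines from the best scan points. Approximate 95% confidence intervals per
parameter come from profiling: the parameter sweeps a log-spaced grid (two
decades; integers for npop) with the others held at the optimum, and the CI
is the extremal grid span with relative likelihood ≥ exp(−χ²₀.₉₅,₁/2)
≈ 0.1465, always containing the best value.

## Recursive demarcation

`demarcate` walks a rooted tree (neighbor joining on corrected distances,
midpoint-rooted, via scikit-bio — or a user tree, optionally outgroup-
rooted) depth-first from the root. For each clade it asks for the
maximum-likelihood ecotype count of the clade's own binning curve, holding
`omega` and `sigma` at the global fit and scanning integer npop from 1 to a
cap (12 by default, and never beyond the clade's distinct-sequence count
plus one). A clade is demarcated as one putative ecotype when the
single-population hypothesis is **not rejected** — npop = 1 lies inside the
same 0.1465 relative-likelihood band used for the profile CIs — otherwise
the walk descends into the children. Two further rules keep the recursion
honest about what the data can resolve:

* **Resolution floor.** A clade that is a single bin at every criterion at
  or below 0.995 shows structure only at the microheterogeneity scale,
  where the curve is governed by the (noisily estimated) periodic-selection
  rate; such clades are demarcated whole without simulation. The floor is
  `DemarcationConfig.structure_criterion`; lowering it trades resolution of
  very recently diverged populations against the risk of shattering a
  single population when the rates are misfit.
* **Unexplained clades descend.** If no ecotype count achieves positive
  likelihood on a structured clade, the walk descends rather than lumping —
  a rate misfit should not hide real structure.

The result is always a partition of the leaves into clades of the tree, so
every putative ecotype is monophyletic by construction.

## In-silico PCR and RFLP

Primer matching uses IUPAC base-set semantics (a primer position matches a
template position when the base sets intersect), scans both strands, and
counts mismatches uniformly across positions — no 3′-end weighting, which
suffices for the perfect-match screening the primers were designed for. PCR
products pair a plus-strand forward hit with a downstream minus-strand
reverse hit (the reverse primer is given 5′→3′ as synthesized). Restriction
digestion knows MspI (C^CGG) and HhaI (GCG^C), cuts at every occurrence
left-to-right (both sites are palindromic, so strand choice is immaterial),
and always returns fragment lengths summing to the template. RFLP types are
the transitive closure of gel-equivalence: equal fragment counts per enzyme
and each size-ordered fragment pair within 5% (relative to the larger
fragment, absolute floor 4 nt — roughly 2% agarose resolution). The primer
table used throughout the hot-spring screen ships as packaged data.

## Fragment-based ANI

Genomes are chopped into consecutive non-overlapping 1020-nt fragments
(never spanning record boundaries); each fragment is placed on the other
genome by exact 15-mer seeding onto candidate diagonals followed by a
banded semi-global edit-distance alignment (edlib), on both strands, and
retained when it matches at ≥ 70% identity over ≥ 70% of its length. One-way
ANI is the mean identity of retained fragments; two-way ANI averages the two
directions. These are the conventional "standard settings" of web ANI
calculators; all four numbers are configurable. The seeded banded aligner
stands in for BLAST and is adequate in the ≥ 70%-identity regime the filter
keeps; identity is computed as 1 − edit_distance/fragment_length, which
counts indels against identity. Self-comparison returns exactly 100.

## Clade-environment association

Whether demarcated clades track temperature or pH is tested with η² (the
between-group fraction of the total sum of squares) against a permutation
null that relabels values over groups, with the add-one estimator
p = (1 + #{η²_perm ≥ η²_obs}) / (1 + N). The statistic is deliberately
generic — the underlying observation being formalised is a qualitative
clade-by-environment correspondence, and reports label it as such. Ranged
field measurements ("37–40 °C") are encoded by their midpoint with both
bounds retained.

## Synthetic data: what it does and does not show

The alignment generator drives the simulator itself with a balanced, known
lineage-to-ecotype assignment and parameters solved from the target regime:
`sigma = 4/within_div` (putting the mean within-ecotype divergence at half
the configured ceiling), `omega = 0`, and depth chosen so between-ecotype
divergence lands ~15% above the configured floor. Draws are rejected until
the realised divergences respect the bounds (within ≤ 1.2× the ceiling,
minimum between ≥ 0.8× the floor; up to 500 retries — acceptance per draw
is only ~10–20% at the default regime because the within bound allows at
most 2 differing sites at L = 750). Defaults mirror the hot-spring study
regime: a few tenths of a percent within ecotypes (1–3 nt
microheterogeneity), ≥ 3% between.

The recovery experiments (fit → demarcate on 40 sequences of 750 nt at
npop ∈ {1, 2, 4, 6}, R = 200) recover the generating ecotype count in
≥ 80% of seeded runs with profile-CI coverage ≥ 90%. What this does **not**
show: performance on real libraries with alignment error, chimeras, intra-
genomic operon variation, rate heterogeneity across sites, recombination,
or ecotypes separated by less than ~0.5% (below the demarcation's default
resolution floor). The generator's in-model data are the easiest case the
method should ever see; the experiments validate the machinery, not the
biology.

## Numerical and reproducibility notes

* Every stochastic entry point takes an explicit integer seed; derived
  streams use `numpy.random.SeedSequence([seed, tag])`, keeping all seeds
  below 2³¹. Identical seeds give byte-identical pipeline outputs.
* Agglomeration ties in binning are resolved by scipy's deterministic merge
  order; bin counts are tie-insensitive in all tested cases.
* Negative neighbor-joining branch lengths are clamped to zero (logged);
  midpoint rooting falls back to the NJ root on degenerate all-zero trees.
* p-distances at or beyond the Jukes–Cantor saturation bound (0.75) raise a
  dedicated error rather than returning infinities.
* Problem sizes in the shipped experiments (40 sequences, L = 750, R = 200,
  200-dataset null calibration, 150-kb genomes) were chosen as the smallest
  sizes at which the statistical claims are comfortably testable.
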