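# ecotyping

Model-based demarcation of closely related bacterial populations from 16S
rRNA gene libraries, with the surrounding screens a diversity survey needs.

Surveys of environmental bacteria — for instance green sulfur bacteria in
hot-spring microbial mats — routinely recover clouds of nearly identical 16S
sequences: tight clusters differing internally by 1–3 nt
(microheterogeneity) and separated from each other by 0.2–4%. Deciding which
clusters are distinct *ecological* populations is not answerable by identity
thresholds alone. This package implements the Stable-Ecotype-Model approach:
summarise the library as a **binning curve** (number of sequence clusters as
a function of the identity criterion), fit an evolutionary model to that
curve by Monte-Carlo simulation, and recursively walk the phylogeny to find
the clades whose maximum-likelihood ecotype count equals one — the putative
ecotypes.

The model has three parameters: the ecotype-formation rate ω, the
periodic-selection rate σ (each sweep purges one ecotype's diversity), and
the number of ecotype populations n_pop, all rates per unit branch length
(substitutions/site). Backward in time, each ecotype with ≥ 2 sampled
lineages coalesces completely at rate σ, ecotypes merge at rate ω, and the
likelihood of (ω, σ, n_pop) is the fraction of simulated genealogies —
evolved into sequences under Jukes–Cantor, with per-branch substitution
probability p(b) = (3/4)(1 − e^(−4b/3)) — whose binning curve matches the
observed one within a multiplicative tolerance. Fitting is Nelder–Mead over
log-parameters with profile-likelihood 95% confidence intervals.

Around that core the package provides:

* `seq_core` — aligned FASTA I/O, pairwise-deletion p-distances,
  Jukes–Cantor correction, group divergence summaries, clone tallies, and
  the dilution-to-extinction density bound;
* `binning` — binning curves by complete-linkage clustering;
* `ecosim` / `fit_demarcate` — the simulator, likelihood, Nelder–Mead fit,
  profile CIs, neighbor-joining trees, and the recursive demarcation;
* `amplicon` — in-silico PCR with IUPAC-degenerate primers (the 16S primer
  set used for green-sulfur-bacteria screening ships as packaged data) and
  MspI/HhaI RFLP typing;
* `ani` — fragment-based two-way average nucleotide identity between
  genomes (1020-nt fragments, 70%/70% retention, edlib alignment);
* `envcorr` — permutation η² tests of clade-by-environment association,
  plus the study-site metadata table;
* `synthetic_data` — seed-deterministic generators with known ground truth
  for every stage;
* `ecotyping` CLI — `distances`, `bin`, `fit`, `demarcate`, `pcr`, `rflp`,
  `ani`, `envassoc`, `simulate`, `pipeline`.

## Worked example

Generate a ground-truthed library of four ecotypes (40 sequences, 750 nt,
≤ 0.3% within, ≥ 3% between), fit the model, demarcate, and test the
temperature association:

```python
from ecotyping import binning_curve, distance_matrix, fit_parameters, nj_tree, demarcate
from ecotyping.fit_demarcate import DemarcationConfig, default_depth
from ecotyping.envcorr import clade_env_association
from ecotyping.synthetic_data import (
    SynthConfig, simulate_ecotype_alignment, simulate_site_metadata,
)

cfg = SynthConfig(n_ecotypes=4, seqs_per_ecotype=10, L=750, seed=42)
aln, truth = simulate_ecotype_alignment(cfg)

dm_p = distance_matrix(aln, kind="p_distance")
dm_jc = distance_matrix(aln, kind="jc_corrected")
curve = binning_curve(dm_p)
print("binning curve:", dict(zip(curve.criteria, curve.n_bins)))

fit = fit_parameters(curve, n=len(aln), depth=default_depth(dm_jc.data),
                     L=aln.length, R=200, restarts=1, seed=42)
print(f"fitted: npop={fit.best.npop} sigma={fit.best.sigma:.0f} "
      f"omega={fit.best.omega:.3g} likelihood={fit.likelihood:.2f}")

dem = demarcate(nj_tree(dm_jc), aln, fit, DemarcationConfig(seed=42))
print(f"demarcated {dem.n_ecotypes()} putative ecotypes")

meta = simulate_site_metadata(truth, seed=42)
res = clade_env_association(dem.assignments, meta, "temperature_c", seed=42)
print(f"temperature association: eta2={res.statistic:.3f} p={res.p_value:.4f}")
```

Output:

```
binning curve: {1.0: 13, 0.995: 4, 0.99: 4, 0.98: 4, 0.97: 4, 0.96: 2, 0.95: 1, 0.9: 1, 0.85: 1, 0.8: 1}
fitted: npop=4 sigma=5067 omega=0.541 likelihood=0.06
demarcated 4 putative ecotypes
temperature association: eta2=0.990 p=0.0010
```

Reading it: the library collapses to 13 distinct sequences, holds 4 clusters
across the 99.5–97% identity range, and merges below 96% — the signature of
four tight populations. The fit recovers n_pop = 4 with a high
periodic-selection rate (tight within-cluster diversity); 6% of simulated
replicates reproduce the curve within tolerance, and the recursive walk
demarcates exactly the four generated ecotypes (each demarcated clade
coincides with one true ecotype). The demarcated partition explains 99% of
the temperature variance across sites, with the permutation p-value at its
add-one floor.

The same analysis runs from the shell:

```bash
ecotyping simulate --n-ecotypes 4 --seqs-per-ecotype 10 --seed 42 --outdir fix/
ecotyping pipeline --alignment fix/alignment.fasta --metadata fix/metadata.tsv \
                   --seed 42 --outdir out/
```

writing distance matrices, the binning curve, the fit, a newick tree, the
demarcation table and association report, plus a manifest recording every
parameter and seed; reruns with the same seed are byte-identical.

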