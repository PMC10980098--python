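# pepforge

Structure-guided peptide design by multi-objective Bayesian optimization.

## The problem

Designing a peptide that binds a target protein means searching an enormous
discrete sequence space with an expensive oracle: each candidate must be
folded into a complex with the target and judged on structural grounds.
`pepforge` packages that loop for desk-scale use. It scores protein–peptide
complex structures with three bespoke interface objectives and drives a
Gaussian-process surrogate with a noisy-expected-hypervolume-improvement
acquisition over mutated peptide sequences, so that far fewer structures
need to be evaluated than brute-force mutagenesis would require. It is
aimed at computational structural biologists prototyping design campaigns
and at anyone who needs the individual pieces — interface SASA, binding-site
ratios, 2-D hypervolume, TM-score — as clean, tested primitives.

## The model

**Objectives** (any two drive a run; directions are configurable):

- *Buried interface SASA* — Shrake–Rupley solvent-accessible surface area
  with probe radius 1.4 Å on a deterministic 960-point golden-spiral
  lattice, combined as
  `SASA(protein) + SASA(peptide) − SASA(complex)`:
  the surface hidden by binding, in Å². Default: maximize.
- *Stability energy* — a square-well contact potential over inter-chain
  heavy-atom pairs (−1 per pair in the 2.5–5 Å window, +10 per clash below
  2.5 Å); lower is more stable. Any external physics-based calculator can be
  substituted through a subprocess adapter. Default: minimize.
- *Binding-site ratio* — residues of one chain within 5 Å (minimum
  heavy-atom distance, strict inequality) of the partner chain, divided by
  the chain length. Default: maximize.

**Optimizer.** Sequences are embedded as per-residue physicochemical
descriptors (hydropathy, charge, volume, polarity) plus one-hot identity,
zero-padded to fixed dimension. Each objective gets an independent exact GP
with a squared-exponential kernel, hyperparameters by regularized marginal
likelihood from a deterministic restart grid. Acquisition is NEHVI: per
Monte-Carlo draw, the posterior is sampled jointly at all observed points
(a sampled "noiseless" Pareto front) and at the candidates, and each
candidate is credited the hypervolume its sample adds; candidates are
discrete mutants of the current Pareto-front parents. Every round's batch
is structure-predicted (template threading by default, pluggable provider
otherwise), scored, and appended to a growth-only pool.

**Evaluation.** Kabsch superposition, positional TM-score
(`TM = (1/L) Σ 1/(1+(dᵢ/d₀)²)`, `d₀ = 1.24(L−15)^⅓ − 1.8` floored at 0.5 Å
for short chains), and a recovery report: the percentage of archive
sequences whose peptide-side binding-site count exactly matches the
native's.

## Worked example

```bash
python examples/03_native_recovery.py
```

prints (exactly; the run is deterministic):

```
native peptide        : LKWFAN
BO final hypervolume  : 172.0
random final hv       : 147.3
BO found native       : True

binding-site match    : 30.2% of 96 sequences keep the native's 6 peptide-side sites
best TM-score         : 1.000 (LKWHAR)
```

The landscape here is a synthetic complex in which every mutation away from
the native 6-mer strictly shrinks the buried interface (verified by
exhaustive single-mutant enumeration), so the native sequence is the known
global optimum. At an identical evaluation budget (16 seeds + 10 rounds ×
8), the BO arm dominates a larger objective-space area than the random arm
(172.0 vs 147.3) and rediscovers the native sequence exactly; 30.2% of all
sequences it evaluated preserve the native's six peptide-side binding
sites. Other capabilities are shown in `examples/01_score_interface.py`
(objective scoring + PDB round trip), `02_optimize_peptide.py` (the round
loop and its hypervolume trace) and `04_external_energy_adapter.py`
(external calculator contract). The same functionality is exposed on the
command line: `pepforge score`, `pepforge optimize`, `pepforge evaluate`,
`pepforge fixtures make-toy`.

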