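# Methods

## Structural model

A complex is two chains of residues, each residue an ordered set of heavy
atoms with Cartesian coordinates (Å) and van der Waals radii. Parsing keeps
ATOM records only: HETATM entries, waters and hydrogens are dropped, since
crystallographic structures rarely carry hydrogens and the heavy-atom radii
set assumes their absence. Alternate locations resolve to the highest
occupancy (first encountered on ties); only the first model of multi-MODEL
files is read; insertion codes order lexicographically after the residue
number and never collapse residues. Radii default to Bondi-style values
(C 1.70, N 1.55, O 1.52, S 1.80, default 1.70 Å) and are table-overridable.

Residue–residue distance is the minimum over heavy-atom pairs — the
convention behind the 5 Å contact cutoff in the interface literature — with
a Cα-only mode available in the run config (`contact_atoms: ca`).

## Objectives

**Buried interface SASA.** Shrake–Rupley with probe 1.4 Å: each atom's
sphere of radius `r + probe` is discretized by a golden-spiral (Fibonacci)
lattice — deterministic, so no seed is needed — and a lattice point counts
as exposed when outside every other expanded sphere. The default lattice
size is 960 points, giving ≤0.2% error against the analytic isolated-sphere
and two-sphere spherical-cap values and <2% against an independent
reference implementation; 240 points (used by the desk-scale studies for
speed) stays within ~1%. Burial is
`SASA(protein) + SASA(peptide) − SASA(complex)` on the rigid split
(partner atoms deleted, no re-relaxation). Discretization can make the
difference marginally negative for non-contacting chains; values are
clamped at 0 with the raw number kept in the debug log. Neighbour search
prunes with a KD-tree at the maximal occlusion distance and is tested to be
identical to the all-pairs scan.

On sign conventions: a larger buried interface indicates a more engaging
binding mode, so the default direction for this objective is *maximize*.
Because practice varies (some groups minimize a complex-SASA proxy), the
direction of every objective is an explicit config field rather than a
hard-coded assumption.

**Stability energy.** The built-in stand-in for a physics-based stability
calculator is a square-well contact potential over inter-chain heavy-atom
pairs: −`well_depth` (default 1.0) for pairs in `[clash, contact)` =
[2.5 Å, 5.0 Å), +`clash_penalty` (default 10.0) below 2.5 Å, zero beyond.
Units are arbitrary: the GP standardizes objectives, so only candidate
ordering matters. Only inter-chain terms are scored — the objective tracks
interaction stability, not intra-chain strain. Users with a licensed
calculator plug it in through the adapter contract (any command taking a
PDB path and printing a scalar; the last whitespace-delimited stdout token
is parsed, and every failure mode raises instead of defaulting).

**Binding sites.** A protein and peptide residue pair is a binding pair
when its minimum heavy-atom distance is strictly below the cutoff
(default 5 Å). The per-chain binding ratio divides the number of unique
contacting residues by the chain length. When a single scalar objective is
needed the protein-side ratio is used by default; peptide-side or the mean
are selectable, since either chain's ratio is a defensible choice and the
convention is not standardized.

## Optimizer

**Embedding.** Each residue maps to a 24-dim block — Kyte–Doolittle
hydropathy/4.5, formal charge (±1, His 0.5), residue volume normalized by
tryptophan's, a polarity flag, and a one-hot identity — concatenated over
positions, zero-padded to the run's maximum length, with a relative-length
feature appended. Deterministic, local (a substitution changes exactly one
block), and decoder-free: candidate generation happens in sequence space,
so no inverse mapping is ever needed. This replaces learned autoencoder
embeddings deliberately — it removes any trained-weights dependency while
preserving the contract BO needs (discrete sequence → fixed continuous
vector).

**GP surrogate.** One independent exact GP per objective (no
inter-objective covariance, which would add hyperparameters the small
per-round datasets cannot support), squared-exponential kernel, objectives
standardized internally. Hyperparameters maximize the marginal likelihood
with analytic gradients from three deterministic restarts around the median
inter-point distance. The likelihood alone is degenerate in the
short-length-scale regime (only `σf² + σn²` is identified there), so weak
log-normal hyperpriors regularize the fit: length scale centered on the
median spacing (σ=1.5), signal variance on 1, noise on 1e-4 (σ=2) — the
noise prior breaks the ridge toward near-noiseless fits, which is what
interpolating noiseless objective evaluations requires. Identical training
inputs get jitter and a warning rather than an error.

**Pareto machinery.** Maximize-all canonical form (minimized objectives
negated on ingest). Dominance is ≥ in both coordinates and > in one;
duplicates never dominate each other. 2-D hypervolume is the exact
staircase sweep; NEHVI is Monte-Carlo joint posterior sampling: per draw,
sample all observed points and candidates jointly per objective, take the
sampled observed values as the "noiseless" front, and credit each candidate
the area its sample adds (computed by a vectorized staircase-contribution
formula, zero when the sample fails to dominate the reference point).
Estimates are non-negative by construction and deterministic per seed;
n_mc defaults to 128. The reference point is the componentwise minimum of
observed canonical objectives minus 10% of the observed range, recomputed
each round for acquisition; the *logged* archive hypervolume uses the
reference point frozen after seeding so its trace is comparable (and
provably non-decreasing) across rounds.

**Loop.** Defaults mirror a full campaign: 64 rounds × batch 16. Seeds are
unique random mutants of the native peptide (default 16 at Hamming
distance 2, re-drawn on collision with bounded retries). Each round refits
the GP from scratch (warm starts would couple rounds and break
reproducibility), generates up to `n_candidates` (default 256) one-mutants
of the Pareto-front parents, ranks them by NEHVI with lexicographic
tie-break, predicts structures for the top batch, scores, and appends.
Provider failures mark the record failed and continue; an exhausted mutant
neighbourhood yields a smaller batch with a warning. Per-round summaries
log min/max/mean of each objective over the new batch, the pool-wide best,
and the archive hypervolume. Runs are byte-deterministic: all randomness
derives from the config seed (round seeds are `seed + 7919·round` mod 2³¹).

**Structure provider.** The default provider threads a candidate sequence
onto the native backbone: unmutated residues untouched; a mutated residue
keeps its backbone and replaces its side chain with one pseudo-atom at the
template Cβ position whose radius scales with residue volume
(0.8–2.0 Å from Gly to Trp). Threading is a deliberate desk-scale
surrogate for a learned complex predictor; the `StructureProvider` contract
(protein sequence, peptide sequence → complex) is the integration point for
a real prediction service, and the CLI accepts an external command adapter
for that purpose.

## Synthetic data

`make_toy_complex` builds an extended protein backbone (Cα spacing 3.8 Å,
one pseudo side-chain atom per residue) with a parallel peptide: docked at
a chosen side-chain gap (default 4.5 Å, inside the 5 Å contact cutoff),
separated by 100 Å, or clashing (0.5 Å side-chain overlap). Coordinates
carry 0.15 Å seeded jitter so different seeds give genuinely different
geometries without crossing contact thresholds. What these toys emulate is
the *bookkeeping* of real complexes — two chains, an interface, decoys with
known properties — not their physics: there is no secondary structure, no
rotamers, no realistic packing. Tests passing on them demonstrate that the
geometry, scoring and optimization machinery is correct, not that the
objectives rank real binders.

`make_recovery_landscape` turns a docked toy into a sequence-sensitive
provider: peptide side-chain pseudo-atoms point at the protein, and a
substitution at position j retreats its atom by
`min(6, 0.05·|ΔV| + 0.3)` Å and shrinks its radius by `0.004·|ΔV| + 0.05`
(floored at 0.8 Å), where ΔV is the residue-volume difference to the
native. Every substitution therefore strictly reduces buried SASA, and
retreats past the contact window also lose a favourable contact, so both
objectives degrade monotonically in Hamming distance and the native
sequence is the global optimum — verified in the tests by exhaustive 19·L
single-mutant enumeration plus sampled multi-mutant reversion checks. The
smooth volume term is what gives the GP a learnable gradient; the fixed
mismatch term guarantees strictness for near-identical volumes (e.g.
Leu/Ile).

## Desk-scale study conditions

Full campaigns (64×16 with a GPU structure predictor) are out of reach of
a laptop-scale test suite, so the validation studies fix these sizes:

- determinism check: 5 rounds × batch 4 on a toy complex, 6 seeds;
- recovery study: 6-mer native, 16 seeds at Hamming 2, 10 rounds × batch 8,
  128 candidates/round, n_mc 128, SASA at 240 lattice points; 10 trials,
  each paired with a uniform-random arm at the identical budget and
  reference point.

With those conditions the BO arm reaches a higher final hypervolume than
random in ≥8/10 trials and rediscovers the native sequence in ≥7/10 —
computed fresh by `scripts/acceptance.py` and asserted by the test suite.

## Evaluation metrics

Kabsch superposition is closed-form SVD with reflection correction;
collinear or <3-point inputs are rejected since the rotation is then
underdetermined. TM-score uses positional correspondence — candidates share
the native peptide length by construction, so no alignment search is
implemented (a documented limitation versus full structural aligners) —
with the standard `d₀(L) = 1.24(L−15)^⅓ − 1.8` and a 0.5 Å floor for
L ≤ 21, where the formula is non-positive; peptides live almost entirely in
that floored regime. Superposition defaults to the full-complex Cα set,
with a peptide-only mode. The recovery report's match rate uses the
peptide-side binding-site count. Note that under the default threading
provider every candidate keeps the native backbone, so TM-scores of 1.0
are expected there; TM only discriminates when structures come from a real
predictor.

## Known limitations

- Template threading cannot register sequence-dependent backbone changes;
  it is a contract placeholder, not a predictor.
- The contact potential has no electrostatics, solvation or side-chain
  detail; it orders candidates on the synthetic landscapes it was designed
  for and makes no claim on real energetics.
- Exactly two objectives; the hypervolume sweep and NEHVI contributions are
  2-D-specific by design.
- No mmCIF, ligands, or assemblies beyond one protein + one peptide chain.
- The embedding is untrained; on real data a learned representation may be
  strictly better, and the embedding contract allows swapping one in.
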