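"""Run a small multi-objective BO campaign over mutated peptide sequences.

Seeds a pool of mutants of the toy complex's native peptide, then runs five
rounds in which a GP surrogate per objective is fit on all scored sequences,
candidate mutants of the Pareto-front parents are ranked by noisy expected
hypervolume improvement, and the top batch is "predicted" by threading onto
the native backbone and scored on buried SASA (maximized) and contact
energy (minimized).
"""

from pepforge import RoundConfig, run_optimization
from pepforge.fixtures import ToySpec, make_toy_complex

native = make_toy_complex(ToySpec(rng_seed=2))
config = RoundConfig(
    n_rounds=5, batch_size=4,          # desk-scale version of a 64x16 campaign
    n_seeds=6, mutations_per_seed=1,
    n_candidates=48, n_mc=32, n_points=240,
    seed=17,
)
archive = run_optimization(native, config)

print(f"native peptide : {native.peptide_sequence}")
print(f"pool size      : {len(archive.records)} unique sequences")
cols = ["round", "n_new", "interface_sasa_pool_best", "energy_pool_best", "hypervolume"]
print(archive.summaries[cols].to_string(index=False))
print("\nhypervolume is the objective-space area the archive dominates; it can")
print("only grow because the pool only grows. pool_best columns track the best")
print("buried-SASA (max) and contact-energy (min) seen so far.")
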