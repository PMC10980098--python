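"""Score a protein-peptide complex: buried interface SASA, stability, binding sites.

Builds a small synthetic docked complex (a 10-residue protein with a 6-mer
peptide bound 4.5 Å away), round-trips it through PDB text the way a real
structure would be loaded, and prints the three structural objectives.
"""

from pepforge import (
    binding_pairs,
    binding_ratio,
    contact_energy,
    interface_buried_sasa,
    parse_pdb,
    write_pdb,
)
from pepforge.fixtures import ToySpec, make_toy_complex

complex = make_toy_complex(ToySpec(rng_seed=1))
complex = parse_pdb(write_pdb(complex), "A", "B")  # same path a PDB file takes

buried = interface_buried_sasa(complex)
energy = contact_energy(complex)
pairs = binding_pairs(complex, cutoff=5.0)

print(f"peptide sequence      : {complex.peptide_sequence}")
print(f"buried interface SASA : {buried:8.2f} A^2   (surface hidden by binding; bigger = larger interface)")
print(f"contact energy        : {energy:8.2f}       (square-well score; lower = more stable interface)")
print(f"binding pairs (<5 A)  : {sorted(pairs.pairs)}")
print(f"protein binding ratio : {binding_ratio(complex, 'protein'):.2f}  (fraction of protein residues touching the peptide)")
print(f"peptide binding ratio : {binding_ratio(complex, 'peptide'):.2f}  (fraction of peptide residues touching the protein)")
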