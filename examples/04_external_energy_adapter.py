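"""Plug an external energy calculator into the stability objective.

Any executable that accepts a PDB path and prints a scalar can replace the
built-in contact potential — this is the integration point for a licensed
physics-based stability calculator. Here a tiny mock adapter stands in: it
receives the complex as a temporary PDB file and prints an energy.
"""

import sys

from pepforge import external_energy
from pepforge.fixtures import ToySpec, make_toy_complex

complex = make_toy_complex(ToySpec(rng_seed=1))

# a mock adapter: counts ATOM records and reports a fake energy from them
mock = [
    sys.executable,
    "-c",
    "import sys; n = sum(1 for l in open(sys.argv[1]) if l.startswith('ATOM')); "
    "print('mock stability for', n, 'atoms:', -0.5 * n)",
]

energy = external_energy(complex, mock)
print(f"adapter returned energy: {energy}")
print("the adapter contract parses the last whitespace-delimited stdout token;")
print("missing executables, non-zero exits and unparseable output all raise")
print("AdapterError rather than silently defaulting.")
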