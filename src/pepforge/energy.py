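"""Complex-stability objective: a contact potential plus an external-calculator adapter.

The built-in model is a square-well contact potential over inter-chain heavy
atom pairs: pairs inside the favourable window ``[clash_distance,
contact_distance)`` each contribute ``-well_depth``; pairs closer than the
clash distance are penalized by ``+clash_penalty``. Units are arbitrary —
only the ordering of candidates matters to the optimizer, which standardizes
objectives internally. Lower values mean a more stable interface, matching
the -dG convention of physics-based calculators.

For users with a licensed physics-based energy calculator (e.g. an empirical
force field binary), :func:`external_energy` shells out to any command that
accepts a PDB path and prints a scalar; its last whitespace-delimited stdout
token is parsed as the energy.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AdapterError
from .structures import ComplexStructure, write_pdb

__all__ = ["ContactPotential", "contact_energy", "external_energy"]


@dataclass(frozen=True)
class ContactPotential:
    """Square-well inter-chain potential (arbitrary energy units)."""

    well_depth: float = 1.0
    contact_distance: float = 5.0  # Å, aligned with the binding-site cutoff
    clash_distance: float = 2.5  # Å
    clash_penalty: float = 10.0

    def __post_init__(self):
        if not self.clash_distance < self.contact_distance:
            raise ValueError("clash_distance must be below contact_distance")


DEFAULT_POTENTIAL = ContactPotential()


def contact_energy(
    complex: ComplexStructure, pot: ContactPotential = DEFAULT_POTENTIAL
) -> float:
    """Sum the square-well potential over all inter-chain heavy-atom pairs.

    Deterministic; exactly 0 once the chains are separated beyond the
    contact distance.
    """
    p = np.vstack([r.coords() for r in complex.protein])
    q = np.vstack([r.coords() for r in complex.peptide])
    d = cdist(p, q)
    n_clash = int((d < pot.clash_distance).sum())
    n_contact = int(((d >= pot.clash_distance) & (d < pot.contact_distance)).sum())
    return pot.clash_penalty * n_clash - pot.well_depth * n_contact


def external_energy(complex: ComplexStructure, adapter_command: list[str]) -> float:
    """Invoke an external energy calculator on the complex and parse one scalar.

    The complex is written to a temporary PDB file whose path is appended to
    ``adapter_command``. The adapter must exit 0 and print the energy as the
    last whitespace-delimited token on stdout. Any failure raises
    :class:`AdapterError` — there is no silent default.
    """
    if not adapter_command:
        raise AdapterError("no adapter command configured")
    with tempfile.TemporaryDirectory() as tmp:
        pdb_path = Path(tmp) / "complex.pdb"
        pdb_path.write_text(write_pdb(complex))
        try:
            proc = subprocess.run(
                [*adapter_command, str(pdb_path)],
                capture_output=True,
                text=True,
                check=False,
            )
        except FileNotFoundError as exc:
            raise AdapterError(f"adapter executable not found: {exc}") from None
        if proc.returncode != 0:
            raise AdapterError(
                f"adapter exited with status {proc.returncode}: {proc.stderr.strip()[:200]}"
            )
        tokens = proc.stdout.split()
        if not tokens:
            raise AdapterError("adapter produced no output")
        try:
            return float(tokens[-1])
        except ValueError:
            raise AdapterError(
                f"could not parse adapter output {tokens[-1]!r} as a number"
            ) from None
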