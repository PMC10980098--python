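"""Binding-site detection and the per-chain binding-ratio objectives.

A protein residue and a peptide residue form a binding pair when their
minimum heavy-atom distance is strictly below the cutoff (5 Å by default,
the standard contact criterion for protein-peptide interfaces). The binding
ratio of a chain is the fraction of its residues that touch the partner
chain; the binding-site count is the numerator of that fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structures import ComplexStructure

__all__ = ["BindingPairs", "binding_pairs", "binding_ratio", "binding_site_count"]

DEFAULT_CUTOFF = 5.0  # Å


@dataclass(frozen=True)
class BindingPairs:
    """All residue pairs closer than ``cutoff``, keyed by PDB residue numbers."""

    pairs: frozenset  # of (protein_seq_index, peptide_seq_index)
    cutoff: float

    def protein_sites(self) -> set:
        return {p for p, _ in self.pairs}

    def peptide_sites(self) -> set:
        return {q for _, q in self.pairs}


def _min_distance_matrix(complex: ComplexStructure) -> np.ndarray:
    """(n_protein_res, n_peptide_res) matrix of minimum heavy-atom distances."""
    p_coords, p_idx = [], []
    for i, res in enumerate(complex.protein):
        c = res.coords()
        p_coords.append(c)
        p_idx.extend([i] * len(c))
    q_coords, q_idx = [], []
    for j, res in enumerate(complex.peptide):
        c = res.coords()
        q_coords.append(c)
        q_idx.extend([j] * len(c))
    d_atoms = cdist(np.vstack(p_coords), np.vstack(q_coords))
    out = np.full((len(complex.protein), len(complex.peptide)), np.inf)
    np.minimum.at(out, (np.asarray(p_idx)[:, None], np.asarray(q_idx)[None, :]), d_atoms)
    return out


def binding_pairs(complex: ComplexStructure, cutoff: float = DEFAULT_CUTOFF) -> BindingPairs:
    """All and only residue pairs with minimum heavy-atom distance < cutoff."""
    dmat = _min_distance_matrix(complex)
    ii, jj = np.nonzero(dmat < cutoff)  # strict: "closer than" the cutoff
    pairs = frozenset(
        (complex.protein[i].seq_index, complex.peptide[j].seq_index)
        for i, j in zip(ii.tolist(), jj.tolist())
    )
    return BindingPairs(pairs=pairs, cutoff=cutoff)


def binding_site_count(
    complex: ComplexStructure, side: str = "protein", cutoff: float = DEFAULT_CUTOFF
) -> int:
    """Number of unique residues on ``side`` within the cutoff of the partner chain."""
    bp = binding_pairs(complex, cutoff)
    if side == "protein":
        return len(bp.protein_sites())
    if side == "peptide":
        return len(bp.peptide_sites())
    raise ValueError(f"side must be 'protein' or 'peptide', got {side!r}")


def binding_ratio(
    complex: ComplexStructure, side: str = "protein", cutoff: float = DEFAULT_CUTOFF
) -> float:
    """Fraction of the chain's residues in contact with the partner chain, in [0, 1]."""
    n = len(complex.chain(side))
    return binding_site_count(complex, side, cutoff) / n
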