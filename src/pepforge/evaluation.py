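"""Native-recovery metrics: Kabsch superposition, TM-score, match-rate report.

TM-score here assumes positional residue correspondence (candidates share
the native peptide length by construction of the pipeline), so no alignment
search is performed:

    TM = (1/L) sum_i 1 / (1 + (d_i / d0(L))^2)

with the standard normalization d0(L) = 1.24 (L-15)^(1/3) - 1.8 for L > 21
and a 0.5 Å floor for the short chains typical of peptides, where the cube
root formula is non-positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interface import binding_site_count
from .structures import ComplexStructure

__all__ = ["Superposition", "kabsch", "tm_score", "recovery_report", "RecoveryReport"]


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid map x -> R x + t of one point set onto another."""

    rotation: np.ndarray  # 3x3, proper (det = +1)
    translation: np.ndarray  # 3-vector
    rmsd: float  # Å

    def apply(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.rotation.T + self.translation


def kabsch(P: np.ndarray, Q: np.ndarray) -> Superposition:
    """Least-squares optimal proper rotation/translation of P onto Q.

    Reflections are corrected, so the result is always a rigid motion.
    Degenerate (collinear or fewer than 3) point sets are rejected because
    the rotation is not determined by them.
    """
    P = np.atleast_2d(np.asarray(P, float))
    Q = np.atleast_2d(np.asarray(Q, float))
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be equal-shape (N, 3) arrays")
    n = len(P)
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    cP, cQ = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cP, Q - cQ
    # collinear sets leave a free rotation about the line
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def _d0(L: int) -> float:
    if L > 21:
        return 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8
    return 0.5  # short-chain floor used by reference TM-score codes


def _ca_coords(complex: ComplexStructure, align_on: str) -> np.ndarray:
    if align_on == "complex":
        residues = complex.protein + complex.peptide
    elif align_on == "peptide":
        residues = complex.peptide
    else:
        raise ValueError(f"align_on must be 'complex' or 'peptide', got {align_on!r}")
    coords = []
    for res in residues:
        ca = res.atom("CA")
        if ca is None:
            raise ValueError(
                f"residue {res.res_name} {res.seq_index} has no CA atom"
            )
        coords.append(ca.position)
    return np.array(coords)


def tm_score(
    candidate: ComplexStructure, native: ComplexStructure, align_on: str = "complex"
) -> float:
    """Length-normalized structural similarity in (0, 1] after superposition.

    Residue correspondence is positional; a residue-count mismatch is an
    error rather than triggering an alignment search.
    """
    P = _ca_coords(candidate, align_on)
    Q = _ca_coords(native, align_on)
    if len(P) != len(Q):
        raise ValueError(f"selection lengths differ: {len(P)} vs {len(Q)}")
    sup = kabsch(P, Q)
    d = np.linalg.norm(sup.apply(P) - Q, axis=1)
    L = len(Q)
    return float(np.mean(1.0 / (1.0 + (d / _d0(L)) ** 2)))


@dataclass
class RecoveryReport:
    """How close an optimization archive came to the native complex."""

    native_site_count: int  # peptide-side binding sites of the native
    n_candidates: int
    match_rate_pct: float  # % of candidates with exactly the native count
    best_tm: float
    best_tm_sequence: str
    native_recovered: bool  # native sequence present in the archive
    best_per_objective: dict  # objective name -> (sequence, value)
    per_round: pd.DataFrame  # min/max/mean traces per objective

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "native_site_count": self.native_site_count,
                    "n_candidates": self.n_candidates,
                    "match_rate_pct": self.match_rate_pct,
                    "best_tm": self.best_tm,
                    "best_tm_sequence": self.best_tm_sequence,
                    "native_recovered": self.native_recovered,
                }
            ]
        )


def recovery_report(archive, native_complex: ComplexStructure, cutoff: float = 5.0) -> RecoveryReport:
    """Compare every scored archive candidate against the native complex.

    The headline statistic is the percentage of candidates whose peptide-side
    binding-site count exactly matches the native's; the report also carries
    the best TM-score, the best candidate per objective, and the per-round
    objective traces from the run summaries.
    """
    native_count = binding_site_count(native_complex, "peptide", cutoff)
    scored = [r for r in archive.records if r.scored and r.structure is not None]
    if not scored:
        raise ValueError("archive has no scored candidates with structures")

    n_match = 0
    best_tm, best_seq = -1.0, ""
    for r in scored:
        if binding_site_count(r.structure, "peptide", cutoff) == native_count:
            n_match += 1
        tm = tm_score(r.structure, native_complex, align_on="complex")
        if tm > best_tm:
            best_tm, best_seq = tm, r.sequence

    config = archive.config
    best_per_obj = {}
    for k, name in enumerate(config.objectives):
        pick = (max if config.directions[k] == "maximize" else min)(
            scored, key=lambda r: r.objectives.values[k]
        )
        best_per_obj[name] = (pick.sequence, pick.objectives.values[k])

    native_seq = archive.native_peptide
    return RecoveryReport(
        native_site_count=native_count,
        n_candidates=len(scored),
        match_rate_pct=100.0 * n_match / len(scored),
        best_tm=best_tm,
        best_tm_sequence=best_seq,
        native_recovered=any(r.sequence == native_seq for r in scored),
        best_per_objective=best_per_obj,
        per_round=archive.summaries,
    )
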