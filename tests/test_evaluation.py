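"""Kabsch superposition, TM-score and the native-recovery report."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

import pepforge
from pepforge import ComplexStructure, kabsch, recovery_report, tm_score
from pepforge.pipeline import CandidateRecord, OptimizationArchive, RoundConfig, _score_record

from conftest import random_rotation, single_atom_residue


def ca_complex(coords, n_protein):
    """Build a complex whose CA atoms sit exactly at ``coords``."""
    prot = tuple(
        single_atom_residue("A", i + 1, coords[i], name="CA") for i in range(n_protein)
    )
    pep = tuple(
        single_atom_residue("B", i - n_protein + 1, coords[i], name="CA")
        for i in range(n_protein, len(coords))
    )
    return ComplexStructure(protein=prot, peptide=pep)


class TestKabsch:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(5, 3))
        sup = kabsch(P, P)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(sup.translation, 0, atol=1e-9)
        assert sup.rmsd < 1e-9

    def test_recovers_rigid_motion_exactly(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(6, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = P @ R.T + np.array([1.0, -2.0, 3.0])
        sup = kabsch(P, Q)
        assert sup.rmsd < 1e-9
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_reflection_corrected_to_proper_rotation(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(6, 3))
        Q = P.copy()
        Q[:, 2] *= -1  # mirrored target
        sup = kabsch(P, Q)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_beats_rotation_grid_search(self):
        """Closed-form optimum is no worse than any explicitly tried rotation."""
        rng = np.random.default_rng(3)
        P = rng.normal(size=(6, 3))
        Q = rng.normal(size=(6, 3))
        sup = kabsch(P, Q)
        cP, cQ = P.mean(0), Q.mean(0)
        angles = np.arange(0, 360, 30)
        best = np.inf
        for a in angles:
            for b in angles:
                for c in angles:
                    R = Rotation.from_euler("zyx", [a, b, c], degrees=True).as_matrix()
                    d = (P - cP) @ R.T + cQ - Q
                    best = min(best, np.sqrt((d**2).sum() / len(P)))
        assert sup.rmsd <= best + 1e-9

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(8, 3))
        Q = rng.normal(size=(8, 3))
        sup = kabsch(P, Q)
        rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert sup.rmsd == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch(line, line)
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestTMScore:
    def test_identical_structures_score_one(self, docked_toy):
        assert tm_score(docked_toy, docked_toy) == pytest.approx(1.0)

    def test_rigid_motion_invariance(self, docked_toy):
        rng = np.random.default_rng(5)
        moved = docked_toy.transformed(random_rotation(rng), rng.normal(size=3) * 8)
        assert tm_score(moved, docked_toy) == pytest.approx(1.0, abs=1e-6)
        assert tm_score(docked_toy, moved) == pytest.approx(1.0, abs=1e-6)

    def test_constructed_all_distances_at_d0_gives_half(self):
        """30 CA atoms displaced by exactly d0 each -> every term is 1/2."""
        L = 30
        d0 = 1.24 * (L - 15) ** (1 / 3) - 1.8
        theta = 2 * np.pi * np.arange(L) / L
        P = np.column_stack([5 * np.cos(theta), 5 * np.sin(theta), np.zeros(L)])
        Q = P.copy()
        Q[:, 2] = d0 * np.where(np.arange(L) % 2 == 0, 1.0, -1.0)
        assert tm_score(ca_complex(Q, 24), ca_complex(P, 24)) == pytest.approx(0.5, abs=1e-9)

    def test_short_chain_d0_floor(self):
        from pepforge.evaluation import _d0

        assert _d0(6) == 0.5
        assert _d0(21) == 0.5
        assert _d0(30) == pytest.approx(1.24 * 15 ** (1 / 3) - 1.8)

    def test_peptide_only_mode_and_length_mismatch(self, docked_toy):
        assert tm_score(docked_toy, docked_toy, align_on="peptide") == pytest.approx(1.0)
        import dataclasses

        shorter = ComplexStructure(
            protein=docked_toy.protein, peptide=docked_toy.peptide[:-1]
        )
        with pytest.raises(ValueError, match="differ"):
            tm_score(shorter, docked_toy)


class TestRecoveryReport:
    @staticmethod
    def archive_for(sequences, landscape, cfg=None):
        cfg = cfg or RoundConfig(n_points=240)
        records = []
        for s in sequences:
            rec = CandidateRecord(sequence=s, round_index=0)
            _score_record(rec, landscape, landscape.protein_sequence, cfg,
                          len(landscape.native_peptide))
            records.append(rec)
        return OptimizationArchive(
            records=records,
            summaries=pd.DataFrame({"round": [0]}),
            config=cfg,
            reference_point=np.zeros(2),
            native_peptide=landscape.native_peptide,
        )

    def test_native_only_archive_matches_100_percent(self, landscape):
        arch = self.archive_for([landscape.native_peptide], landscape)
        rep = recovery_report(arch, landscape.native_complex)
        assert rep.match_rate_pct == pytest.approx(100.0)
        assert rep.best_tm == pytest.approx(1.0)
        assert rep.native_recovered

    def test_hand_built_quarter_match_rate(self, landscape):
        # native keeps all 6 peptide-side sites; GGGGGG retreats every side
        # chain far out of contact, dropping the count
        seqs = [landscape.native_peptide, "GGGGGG", "GGGGGG"[:5] + "W", "WGGGGG"]
        arch = self.archive_for(seqs, landscape)
        rep = recovery_report(arch, landscape.native_complex)
        native_count = rep.native_site_count
        from pepforge import binding_site_count

        matches = sum(
            binding_site_count(r.structure, "peptide", 5.0) == native_count
            for r in arch.records
        )
        assert rep.match_rate_pct == pytest.approx(100.0 * matches / 4)
        assert matches == 1  # only the native itself matches here

    def test_separated_decoys_never_match(self, landscape):
        import dataclasses

        arch = self.archive_for([landscape.native_peptide], landscape)
        nat = landscape.native_complex
        # pull the peptide 100 Å away: no contacts left, native count is > 0
        moved = tuple(
            dataclasses.replace(
                res,
                atoms=tuple(
                    dataclasses.replace(a, position=a.position + np.array([0, 100.0, 0]))
                    for a in res.atoms
                ),
            )
            for res in nat.peptide
        )
        arch.records[0].structure = ComplexStructure(protein=nat.protein, peptide=moved)
        rep = recovery_report(arch, landscape.native_complex)
        assert rep.native_site_count > 0
        assert rep.match_rate_pct == 0.0
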