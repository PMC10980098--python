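"""Seed mutagenesis, candidate pools, batch proposal and the optimization loop.

One optimization run mirrors a structure-guided design campaign: a seed pool
of mutated copies of the native peptide is scored on two structural
objectives, then each round fits a fresh GP surrogate per objective on the
whole pool, proposes mutants of the Pareto-front parents, ranks them by
NEHVI acquisition, predicts structures for the top batch through a pluggable
:class:`StructureProvider`, scores them, and appends everything to the pool.
The pool only grows, so the archive hypervolume with respect to a fixed
reference point is non-decreasing across rounds. Every random choice is
driven by seeds derived from the config seed, making whole runs — including
the serialized archive — reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Protocol

import numpy as np
import pandas as pd
import yaml

from . import sasa as sasa_mod
from .bo_core import (
    AMINO_ACIDS,
    GPSurrogate,
    LatentEmbedding,
    ObjectiveVector,
    _staircase,
    _hv_from_staircase,
    embed_sequence,
    fit_gp,
    nehvi,
    pareto_front,
)
from .energy import ContactPotential, contact_energy
from .errors import ConfigError
from .interface import binding_ratio
from .structures import Atom3D, ComplexStructure, one_to_three
from .bo_core import RESIDUE_VOLUME

__all__ = [
    "RoundConfig",
    "CandidateRecord",
    "CandidatePool",
    "StructureProvider",
    "OptimizationArchive",
    "mutate_sequence",
    "seed_pool",
    "thread_template",
    "propose_batch",
    "run_optimization",
    "archive_hypervolume",
]

logger = logging.getLogger(__name__)

OBJECTIVE_NAMES = ("interface_sasa", "energy", "binding_ratio")
_DEFAULT_DIRECTIONS = {
    "interface_sasa": "maximize",  # more buried interface = tighter binding
    "energy": "minimize",  # lower contact energy = more stable
    "binding_ratio": "maximize",
}
_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class StructureProvider(Protocol):
    """Contract: (protein sequence, peptide sequence) -> ComplexStructure."""

    def __call__(self, protein_seq: str, peptide_seq: str) -> ComplexStructure: ...


@dataclass
class RoundConfig:
    """Every tunable of an optimization run, flat and serializable.

    Defaults mirror the campaign scale the method was designed around
    (64 rounds of 16 candidates); desk-scale runs shrink ``n_rounds``,
    ``batch_size`` and ``n_candidates``.
    """

    n_rounds: int = 64
    batch_size: int = 16
    objectives: tuple[str, str] = ("interface_sasa", "energy")
    directions: tuple[str, str] | None = None  # None = per-objective defaults
    cutoff: float = 5.0  # Å, binding-site distance
    contact_atoms: str = "heavy"  # heavy | ca residue-distance convention
    binding_side: str = "protein"  # which chain's ratio enters the optimizer
    probe_radius: float = 1.4  # Å
    n_points: int = 960  # sphere lattice size for SASA
    well_depth: float = 1.0
    contact_distance: float = 5.0
    clash_distance: float = 2.5
    clash_penalty: float = 10.0
    n_seeds: int = 16
    mutations_per_seed: int = 2
    include_native: bool = False
    n_candidates: int = 256
    mutations_per_proposal: int = 1
    n_mc: int = 128
    gp_restarts: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_rounds < 1 or self.batch_size < 1:
            raise ConfigError("n_rounds and batch_size must be >= 1")
        if len(self.objectives) != 2:
            raise ConfigError("exactly two objectives are optimized per run")
        for name in self.objectives:
            if name not in OBJECTIVE_NAMES:
                raise ConfigError(
                    f"unknown objective {name!r}; choose from {OBJECTIVE_NAMES}"
                )
        self.objectives = tuple(self.objectives)
        if self.directions is None:
            self.directions = tuple(_DEFAULT_DIRECTIONS[n] for n in self.objectives)
        self.directions = tuple(self.directions)
        if len(self.directions) != 2 or any(
            d not in ("maximize", "minimize") for d in self.directions
        ):
            raise ConfigError("directions must be two of 'maximize'/'minimize'")
        if self.contact_atoms not in ("heavy", "ca"):
            raise ConfigError("contact_atoms must be 'heavy' or 'ca'")
        if self.binding_side not in ("protein", "peptide", "mean"):
            raise ConfigError("binding_side must be 'protein', 'peptide' or 'mean'")
        if not (0 <= self.seed < 2**31):
            raise ConfigError("seed must be a non-negative 31-bit integer")

    @property
    def potential(self) -> ContactPotential:
        return ContactPotential(
            well_depth=self.well_depth,
            contact_distance=self.contact_distance,
            clash_distance=self.clash_distance,
            clash_penalty=self.clash_penalty,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RoundConfig":
        """Load a flat key/value YAML config; unknown keys are errors."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("objectives", "directions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path):
        data = dataclasses.asdict(self)
        data["objectives"] = list(self.objectives)
        data["directions"] = list(self.directions)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class CandidateRecord:
    """One evaluated (or failed) peptide candidate."""

    sequence: str
    round_index: int
    parent: str | None = None
    embedding: LatentEmbedding | None = None
    structure: ComplexStructure | None = None
    objectives: ObjectiveVector | None = None
    failed: bool = False

    @property
    def scored(self) -> bool:
        return self.objectives is not None and not self.failed


class CandidatePool:
    """All candidate records across rounds, unique by sequence, growth-only."""

    def __init__(self):
        self._records: dict[str, CandidateRecord] = {}

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, sequence: str) -> bool:
        return sequence in self._records

    def add(self, record: CandidateRecord):
        if record.sequence in self._records:
            raise ValueError(f"duplicate sequence in pool: {record.sequence}")
        self._records[record.sequence] = record

    def records(self) -> list[CandidateRecord]:
        return list(self._records.values())

    def scored_records(self) -> list[CandidateRecord]:
        return [r for r in self._records.values() if r.scored]

    def sequences(self) -> list[str]:
        return list(self._records)


def mutate_sequence(seq: str, n_mutations: int, rng: np.random.Generator | int) -> str:
    """Substitute exactly ``n_mutations`` positions, uniformly chosen.

    Positions are drawn without replacement; each substitution is uniform
    over the 19 residues differing from the current one. Deterministic for a
    fixed seed/generator state.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if n_mutations > len(seq):
        raise ValueError(f"cannot mutate {n_mutations} positions of a {len(seq)}-mer")
    if n_mutations == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mutations, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [aa for aa in AMINO_ACIDS if aa != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def seed_pool(
    native_peptide: str,
    n_seeds: int,
    mutations_per_seed: int,
    rng_seed: int,
    include_native: bool = False,
) -> CandidatePool:
    """Build the round-0 pool of unique mutants of the native peptide.

    Mutants are re-drawn on collision (bounded retries); the records are
    unscored here and scored by :func:`run_optimization` before round 1.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    rng = np.random.default_rng(rng_seed)
    pool = CandidatePool()
    if include_native:
        pool.add(CandidateRecord(sequence=native_peptide, round_index=0, parent=None))
    max_tries = 200 * n_seeds
    tries = 0
    target = n_seeds + int(include_native)
    while len(pool) < target:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not draw {n_seeds} unique mutants at Hamming distance "
                f"{mutations_per_seed} from a {len(native_peptide)}-mer"
            )
        mutant = mutate_sequence(native_peptide, mutations_per_seed, rng)
        if mutant in pool or mutant == native_peptide:
            continue
        pool.add(CandidateRecord(sequence=mutant, round_index=0, parent=native_peptide))
    return pool


def _pseudo_sidechain_radius(aa: str) -> float:
    """Residue-volume-scaled radius for a single pseudo side-chain atom (Å)."""
    v, v_lo, v_hi = RESIDUE_VOLUME[aa], RESIDUE_VOLUME["G"], RESIDUE_VOLUME["W"]
    return 0.8 + 1.2 * (v - v_lo) / (v_hi - v_lo)


def thread_template(native_complex: ComplexStructure, peptide_seq: str) -> ComplexStructure:
    """Thread a mutated peptide sequence onto the native backbone.

    Unmutated residues are untouched. A mutated residue keeps its backbone
    atoms; its side-chain atoms are replaced by one pseudo-atom at the
    template's Cβ position (or 1.5 Å from Cα along the Cα→Cβ direction when
    only a pseudo side chain exists) with a residue-volume-scaled radius.
    """
    native_seq = native_complex.peptide_sequence
    if len(peptide_seq) != len(native_seq):
        raise ValueError(
            f"peptide length {len(peptide_seq)} != template length {len(native_seq)}"
        )
    if peptide_seq == native_seq:
        return native_complex
    new_peptide = []
    for res, aa in zip(native_complex.peptide, peptide_seq):
        if aa == res.one_letter:
            new_peptide.append(res)
            continue
        if aa not in AMINO_ACIDS:
            raise ValueError(f"invalid amino acid {aa!r}")
        backbone = [a for a in res.atoms if a.name in _BACKBONE_ATOMS and a.name != "CB"]
        ca = res.atom("CA")
        cb = res.atom("CB")
        side = [a for a in res.atoms if a.name not in _BACKBONE_ATOMS or a.name == "CB"]
        if cb is not None:
            pos = cb.position
        elif ca is not None and side:
            d = side[0].position - ca.position
            pos = ca.position + 1.5 * d / np.linalg.norm(d)
        elif ca is not None:
            pos = ca.position + np.array([0.0, 0.0, 1.5])
        else:
            pos = res.coords().mean(axis=0)
        pseudo = Atom3D(
            name="CB", element="C", position=pos, vdw_radius=_pseudo_sidechain_radius(aa)
        )
        new_peptide.append(
            replace(res, res_name=one_to_three(aa), atoms=tuple(backbone) + (pseudo,))
        )
    return ComplexStructure(
        protein=native_complex.protein,
        peptide=tuple(new_peptide),
        source_id=native_complex.source_id + "+threaded",
    )


# ---------------------------------------------------------------------------
# Objective scoring
# ---------------------------------------------------------------------------


def _score_structure(structure: ComplexStructure, config: RoundConfig) -> ObjectiveVector:
    values = []
    for name in config.objectives:
        if name == "interface_sasa":
            values.append(
                sasa_mod.interface_buried_sasa(
                    structure, probe_radius=config.probe_radius, n_points=config.n_points
                )
            )
        elif name == "energy":
            values.append(contact_energy(structure, config.potential))
        else:  # binding_ratio
            if config.binding_side == "mean":
                v = 0.5 * (
                    binding_ratio(structure, "protein", config.cutoff)
                    + binding_ratio(structure, "peptide", config.cutoff)
                )
            else:
                v = binding_ratio(structure, config.binding_side, config.cutoff)
            values.append(v)
    return ObjectiveVector(values=tuple(values), directions=config.directions)


def default_reference_point(Y: np.ndarray) -> np.ndarray:
    """Componentwise minimum minus 10% of the observed range (canonical scale)."""
    Y = np.atleast_2d(Y)
    lo, hi = Y.min(axis=0), Y.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    return lo - 0.1 * span


def archive_hypervolume(Y: np.ndarray, ref: np.ndarray) -> float:
    """Dominated area of a canonical objective set w.r.t. ``ref``.

    Unlike the strict :func:`bo_core.hypervolume_2d`, points that do not
    dominate the reference simply contribute nothing, which is what a
    fixed-reference trace across a growing archive needs.
    """
    xa, ya = _staircase(np.atleast_2d(Y), np.asarray(ref, float))
    return _hv_from_staircase(xa, ya, np.asarray(ref, float))


def propose_batch(
    pool: CandidatePool,
    gp: GPSurrogate,
    config: RoundConfig,
    rng_seed: int,
    max_len: int,
    ref: np.ndarray | None = None,
) -> list[CandidateRecord]:
    """Propose up to ``batch_size`` novel sequences ranked by NEHVI.

    Candidate mutants are generated from Pareto-front parents by
    ``mutate_sequence`` and scored with the acquisition; ties are broken by
    lexicographically smaller sequence. If the neighbourhood is exhausted a
    smaller (possibly empty) batch is returned with a warning.
    """
    scored = pool.scored_records()
    if not scored:
        raise ValueError("pool has no scored records")
    Y = np.array([r.objectives.canonical() for r in scored])
    X = np.array([r.embedding.vector for r in scored])
    front_idx = pareto_front(Y)
    parents = [scored[i] for i in front_idx]

    rng = np.random.default_rng(rng_seed)
    candidates: dict[str, str] = {}  # sequence -> parent
    tries, max_tries = 0, 40 * config.n_candidates
    while len(candidates) < config.n_candidates and tries < max_tries:
        parent = parents[tries % len(parents)]
        tries += 1
        mutant = mutate_sequence(parent.sequence, config.mutations_per_proposal, rng)
        if mutant in pool or mutant in candidates:
            continue
        candidates[mutant] = parent.sequence
    if not candidates:
        warnings.warn("candidate generation exhausted: no novel sequences", stacklevel=2)
        return []
    if len(candidates) < config.batch_size:
        warnings.warn(
            f"only {len(candidates)} novel candidates available "
            f"(batch_size={config.batch_size})",
            stacklevel=2,
        )

    seqs = list(candidates)
    emb = np.array([embed_sequence(s, max_len).vector for s in seqs])
    if ref is None:
        ref = default_reference_point(Y)
    acq = nehvi(emb, gp, X, ref, n_mc=config.n_mc, seed=rng_seed)
    order = sorted(range(len(seqs)), key=lambda i: (-acq[i], seqs[i]))
    chosen = order[: config.batch_size]
    return [
        CandidateRecord(
            sequence=seqs[i],
            round_index=-1,  # set by the caller
            parent=candidates[seqs[i]],
            embedding=LatentEmbedding(vector=emb[i]),
        )
        for i in chosen
    ]


@dataclass
class OptimizationArchive:
    """Everything a run produced: records, per-round summaries, provenance."""

    records: list[CandidateRecord]
    summaries: pd.DataFrame
    config: RoundConfig
    reference_point: np.ndarray
    native_peptide: str

    def scored_records(self) -> list[CandidateRecord]:
        return [r for r in self.records if r.scored]

    def candidate_table(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "sequence": r.sequence,
                "round": r.round_index,
                "parent": r.parent or "",
                "failed": int(r.failed),
            }
            for name, value in zip(
                self.config.objectives,
                r.objectives.values if r.objectives else (np.nan, np.nan),
            ):
                row[name] = value
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path):
        self.candidate_table().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def summaries_to_tsv(self, path: str | Path):
        self.summaries.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def to_fasta(self, path: str | Path):
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">round{r.round_index}|{r.sequence}\n{r.sequence}\n")

    def final_hypervolume(self) -> float:
        Y = np.array([r.objectives.canonical() for r in self.scored_records()])
        return archive_hypervolume(Y, self.reference_point)


def _score_record(
    record: CandidateRecord,
    provider: StructureProvider,
    protein_seq: str,
    config: RoundConfig,
    max_len: int,
):
    if record.embedding is None:
        record.embedding = embed_sequence(record.sequence, max_len)
    try:
        structure = provider(protein_seq, record.sequence)
        record.structure = structure
        record.objectives = _score_structure(structure, config)
    except Exception as exc:  # provider failure: record and move on
        logger.warning("structure provider failed for %s: %s", record.sequence, exc)
        record.failed = True


def run_optimization(
    native_complex: ComplexStructure,
    config: RoundConfig,
    provider: StructureProvider | None = None,
) -> OptimizationArchive:
    """Run the full seeded multi-objective BO loop and return the archive.

    When no provider is given, candidates are threaded onto the native
    backbone with :func:`thread_template`. Per round: fit GP on the scored
    pool, propose a batch by NEHVI, predict structures, score both
    objectives, append to the pool, and log per-round min/max/mean of each
    objective plus the archive hypervolume against a reference point fixed
    after seeding. Fully deterministic for a given config.
    """
    native_peptide = native_complex.peptide_sequence
    protein_seq = native_complex.protein_sequence
    max_len = len(native_peptide)
    if provider is None:
        provider = lambda _p, pep: thread_template(native_complex, pep)  # noqa: E731

    pool = seed_pool(
        native_peptide,
        config.n_seeds,
        config.mutations_per_seed,
        rng_seed=config.seed,
        include_native=config.include_native,
    )
    for record in pool.records():
        _score_record(record, provider, protein_seq, config, max_len)

    scored = pool.scored_records()
    if len(scored) < 2:
        raise RuntimeError("fewer than 2 seeds could be scored; cannot fit a surrogate")
    Y0 = np.array([r.objectives.canonical() for r in scored])
    fixed_ref = default_reference_point(Y0)

    summary_rows = []

    def _log_round(round_index: int, new_records: list[CandidateRecord]):
        scored_all = pool.scored_records()
        Y = np.array([r.objectives.canonical() for r in scored_all])
        row = {"round": round_index, "n_new": len(new_records), "n_pool": len(pool)}
        new_scored = [r for r in new_records if r.scored]
        for k, name in enumerate(config.objectives):
            vals = [r.objectives.values[k] for r in new_scored]
            pool_vals = [r.objectives.values[k] for r in scored_all]
            row[f"{name}_min"] = float(np.min(vals)) if vals else np.nan
            row[f"{name}_max"] = float(np.max(vals)) if vals else np.nan
            row[f"{name}_mean"] = float(np.mean(vals)) if vals else np.nan
            row[f"{name}_pool_best"] = (
                float(np.max(pool_vals))
                if config.directions[k] == "maximize"
                else float(np.min(pool_vals))
            )
        row["hypervolume"] = archive_hypervolume(Y, fixed_ref)
        summary_rows.append(row)

    _log_round(0, pool.records())

    for round_index in range(1, config.n_rounds + 1):
        round_seed = (config.seed + 7919 * round_index) % (2**31)
        scored = pool.scored_records()
        X = np.array([r.embedding.vector for r in scored])
        Y = np.array([r.objectives.canonical() for r in scored])
        gp = fit_gp(X, Y, n_restarts=config.gp_restarts)
        batch = propose_batch(pool, gp, config, round_seed, max_len)
        for record in batch:
            record.round_index = round_index
            _score_record(record, provider, protein_seq, config, max_len)
            pool.add(record)
        _log_round(round_index, batch)
        if not batch:
            logger.warning("round %d proposed no candidates; stopping early", round_index)
            break

    return OptimizationArchive(
        records=pool.records(),
        summaries=pd.DataFrame(summary_rows),
        config=config,
        reference_point=fixed_ref,
        native_peptide=native_peptide,
    )
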