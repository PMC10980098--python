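"""Sequence embedding, GP surrogate, Pareto/hypervolume machinery and NEHVI.

Peptide sequences are mapped to a fixed-dimension continuous embedding
(per-residue physicochemical descriptors plus a one-hot block, zero-padded
to a maximum length). Each objective gets an independent exact Gaussian
process with a squared-exponential kernel, hyperparameters fit by marginal
likelihood. Acquisition is noisy expected hypervolume improvement (NEHVI):
for each Monte-Carlo draw the posterior is sampled jointly at all observed
points (a sampled "noiseless" Pareto front) and at the candidates, and a
candidate is credited with the hypervolume its sampled objective vector adds
to that front. All objectives are handled internally in canonical
maximize-all form; minimized objectives are negated on ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "AMINO_ACIDS",
    "LatentEmbedding",
    "ObjectiveVector",
    "embed_sequence",
    "ExactGP",
    "GPSurrogate",
    "fit_gp",
    "pareto_front",
    "hypervolume_2d",
    "nehvi",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Kyte-Doolittle hydropathy
_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
# Mean residue volumes (Å^3), Zamyatnin-style averages
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}
_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}
_POLAR = set("STNQYCHKRDEW")

_TOKEN_DIM = 4 + len(AMINO_ACIDS)  # descriptors + one-hot


@dataclass(frozen=True)
class LatentEmbedding:
    """Fixed-dimension continuous representation of one peptide sequence."""

    vector: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vector, float)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ValueError("embedding must be a finite 1-D vector")
        object.__setattr__(self, "vector", v)


@dataclass(frozen=True)
class ObjectiveVector:
    """Two objective values with their optimization directions.

    ``canonical()`` returns the maximize-all form used everywhere inside the
    optimizer (minimized objectives negated).
    """

    values: tuple[float, float]
    directions: tuple[str, str]

    def __post_init__(self):
        if len(self.values) != 2 or len(self.directions) != 2:
            raise ValueError("exactly two objectives per run")
        if any(d not in ("maximize", "minimize") for d in self.directions):
            raise ValueError("directions must be 'maximize' or 'minimize'")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        object.__setattr__(self, "directions", tuple(self.directions))

    def canonical(self) -> np.ndarray:
        return np.array(
            [v if d == "maximize" else -v for v, d in zip(self.values, self.directions)]
        )


def _token_block(aa: str) -> np.ndarray:
    block = np.zeros(_TOKEN_DIM)
    block[0] = _HYDROPATHY[aa] / 4.5
    block[1] = _CHARGE.get(aa, 0.0)
    block[2] = RESIDUE_VOLUME[aa] / RESIDUE_VOLUME["W"]
    block[3] = 1.0 if aa in _POLAR else 0.0
    block[4 + _AA_INDEX[aa]] = 1.0
    return block


def embed_sequence(seq: str, max_len: int) -> LatentEmbedding:
    """Deterministic descriptor embedding of a peptide sequence.

    Each residue contributes a block of normalized physicochemical
    descriptors (hydropathy, formal charge, volume, polarity) plus a one-hot
    identity; blocks are concatenated, zero-padded to ``max_len`` tokens, and
    a relative-length feature is appended. Two sequences differing at one
    position differ only in that token's block.
    """
    if len(seq) == 0:
        raise ValueError("sequence must be non-empty")
    if len(seq) > max_len:
        raise ValueError(f"sequence length {len(seq)} exceeds max_len {max_len}")
    for pos, aa in enumerate(seq):
        if aa not in _AA_INDEX:
            raise ValueError(f"invalid amino acid {aa!r} at position {pos}")
    vec = np.zeros(max_len * _TOKEN_DIM + 1)
    for pos, aa in enumerate(seq):
        vec[pos * _TOKEN_DIM : (pos + 1) * _TOKEN_DIM] = _token_block(aa)
    vec[-1] = len(seq) / max_len
    return LatentEmbedding(vector=vec)


# ---------------------------------------------------------------------------
# Gaussian process surrogate
# ---------------------------------------------------------------------------

_JITTER = 1e-10


class ExactGP:
    """Exact GP regression with a squared-exponential (RBF) kernel.

    k(x, x') = signal_variance * exp(-||x - x'||^2 / (2 length_scale^2))
    plus ``noise_variance`` on the diagonal. Targets may be standardized
    internally; posterior outputs are always on the original scale.
    """

    def __init__(
        self,
        length_scale: float = 1.0,
        signal_variance: float = 1.0,
        noise_variance: float = 1e-4,
        standardize: bool = True,
    ):
        self.length_scale = float(length_scale)
        self.signal_variance = float(signal_variance)
        self.noise_variance = float(noise_variance)
        self.standardize = standardize
        self._fitted = False

    # -- kernel -------------------------------------------------------------
    def _k(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        d2 = cdist(A, B, "sqeuclidean")
        return self.signal_variance * np.exp(-0.5 * d2 / self.length_scale**2)

    # -- fitting ------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, optimize: bool = True, n_restarts: int = 3):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float).ravel()
        if len(X) < 2:
            raise ValueError("need at least 2 training points")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if self.standardize:
            self._y_mean = float(y.mean())
            self._y_std = float(y.std())
            if self._y_std < 1e-12:
                self._y_std = 1.0
        else:
            self._y_mean, self._y_std = 0.0, 1.0
        self.X_ = X
        self.y_ = (y - self._y_mean) / self._y_std

        if optimize:
            self._optimize_hyperparameters(n_restarts)
        self._precompute()
        self._fitted = True
        return self

    def _precompute(self):
        n = len(self.X_)
        K = self._k(self.X_, self.X_) + (self.noise_variance + _JITTER) * np.eye(n)
        try:
            self._chol = cho_factor(K, lower=True)
        except np.linalg.LinAlgError:
            # degenerate inputs (e.g. identical rows): inflate jitter
            logger.warning("kernel matrix not PD; adding jitter")
            K += 1e-6 * np.trace(K) / n * np.eye(n)
            self._chol = cho_factor(K, lower=True)
        self._alpha = cho_solve(self._chol, self.y_)

    def _nll_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        log_l, log_sf2, log_sn2 = theta
        ls, sf2, sn2 = np.exp(log_l), np.exp(log_sf2), np.exp(log_sn2)
        n = len(self.X_)
        d2 = cdist(self.X_, self.X_, "sqeuclidean")
        Kr = np.exp(-0.5 * d2 / ls**2)
        K = sf2 * Kr + (sn2 + _JITTER) * np.eye(n)
        try:
            L = cholesky(K, lower=True)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros(3)
        alpha = cho_solve((L, True), self.y_)
        nll = (
            0.5 * float(self.y_ @ alpha)
            + float(np.log(np.diag(L)).sum())
            + 0.5 * n * np.log(2 * np.pi)
        )
        Kinv = cho_solve((L, True), np.eye(n))
        W = Kinv - np.outer(alpha, alpha)  # d(nll)/dK = W/2
        dK_dlogl = sf2 * Kr * (d2 / ls**2)
        grad = np.array(
            [
                0.5 * float((W * dK_dlogl).sum()),
                0.5 * float((W * (sf2 * Kr)).sum()),
                0.5 * float(np.trace(W)) * sn2,
            ]
        )
        # Weak log-normal hyperpriors (MAP). The pure marginal likelihood is
        # degenerate for tiny length scales, where only sf2 + sn2 is
        # identified; a mild pull of the noise toward small values and of the
        # length scale toward the data's median spacing breaks that ridge.
        for idx, (mu, sigma) in enumerate(self._prior_params):
            z = (theta[idx] - mu) / sigma
            nll += 0.5 * z * z
            grad[idx] += z / sigma
        return nll, grad

    def _optimize_hyperparameters(self, n_restarts: int):
        d = pdist(self.X_)
        d_med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
        if not np.any(d > 0):
            logger.warning("all training inputs identical; GP degenerates to noise fit")
        self._prior_params = (
            (np.log(d_med), 1.5),  # length scale ~ data spacing
            (0.0, 2.0),  # signal variance ~ 1 on the standardized scale
            (np.log(1e-4), 2.0),  # noise: weakly pulled toward near-noiseless
        )
        # deterministic restart grid around the median inter-point distance
        starts = [
            (np.log(d_med * m), np.log(1.0), np.log(sn))
            for m, sn in [(1.0, 1e-4), (0.3, 1e-2), (3.0, 1e-1)][: max(1, n_restarts)]
        ]
        best = None
        bounds = [(np.log(1e-3), np.log(1e4)), (np.log(1e-6), np.log(1e4)),
                  (np.log(1e-8), np.log(1e2))]
        for theta0 in starts:
            res = minimize(
                self._nll_and_grad, np.asarray(theta0), jac=True,
                method="L-BFGS-B", bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
        self.length_scale = float(np.exp(best.x[0]))
        self.signal_variance = float(np.exp(best.x[1]))
        self.noise_variance = float(np.exp(best.x[2]))

    @property
    def prior_variance(self) -> float:
        """Signal variance on the original (de-standardized) output scale."""
        return self.signal_variance * getattr(self, "_y_std", 1.0) ** 2

    # -- posterior ----------------------------------------------------------
    def posterior(self, Xq: np.ndarray, full_cov: bool = False):
        """Posterior mean and (co)variance at query points, original scale."""
        if not self._fitted:
            raise RuntimeError("GP is not fitted")
        Xq = np.atleast_2d(np.asarray(Xq, float))
        Ks = self._k(Xq, self.X_)
        mean = Ks @ self._alpha * self._y_std + self._y_mean
        L = self._chol[0]
        V = solve_triangular(L, Ks.T, lower=True)
        if full_cov:
            cov = self._k(Xq, Xq) - V.T @ V
            cov = (cov + cov.T) / 2
            return mean, cov * self._y_std**2
        var = np.clip(np.diag(self._k(Xq, Xq)) - (V**2).sum(axis=0), 0.0, None)
        return mean, var * self._y_std**2

    def sample(self, Xq: np.ndarray, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """(n_draws, len(Xq)) joint posterior draws of the latent function."""
        mean, cov = self.posterior(Xq, full_cov=True)
        cov = cov + _JITTER * max(1.0, self.signal_variance) * np.eye(len(mean))
        try:
            L = cholesky(cov, lower=True)
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh(cov)
            L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
        z = rng.standard_normal((n_draws, len(mean)))
        return mean[None, :] + z @ L.T


@dataclass
class GPSurrogate:
    """Independent exact GPs, one per (canonical, maximize-all) objective."""

    models: tuple[ExactGP, ...]
    X: np.ndarray = field(repr=False, default=None)
    Y: np.ndarray = field(repr=False, default=None)

    @property
    def n_objectives(self) -> int:
        return len(self.models)

    def predict(self, Xq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mean and variance per objective: two (n, n_obj) arrays."""
        means, variances = [], []
        for m in self.models:
            mu, var = m.posterior(Xq)
            means.append(mu)
            variances.append(var)
        return np.column_stack(means), np.column_stack(variances)

    def sample(self, Xq: np.ndarray, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """(n_draws, n_points, n_obj) joint posterior draws, objectives independent."""
        draws = [m.sample(Xq, n_draws, rng) for m in self.models]
        return np.stack(draws, axis=-1)


def fit_gp(X: np.ndarray, Y: np.ndarray, optimize: bool = True, n_restarts: int = 3) -> GPSurrogate:
    """Fit one independent exact GP per objective column of ``Y``.

    ``Y`` must already be canonical (maximize-all). Objectives are
    standardized to zero mean / unit variance internally; hyperparameters are
    set by marginal-likelihood maximization from a deterministic restart grid.
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y row counts differ")
    models = []
    for j in range(Y.shape[1]):
        gp = ExactGP(standardize=True)
        gp.fit(X, Y[:, j], optimize=optimize, n_restarts=n_restarts)
        models.append(gp)
    return GPSurrogate(models=tuple(models), X=X, Y=Y)


# ---------------------------------------------------------------------------
# Pareto front and 2-D hypervolume
# ---------------------------------------------------------------------------


def pareto_front(points: np.ndarray) -> np.ndarray:
    """Indices of non-dominated points (maximize-all convention).

    A point is dominated when some other point is >= in both objectives and
    > in at least one; exact duplicates do not dominate each other, so ties
    are all retained.
    """
    P = np.atleast_2d(np.asarray(points, float))
    if len(P) == 0:
        raise ValueError("need at least one point")
    n = len(P)
    ge = (P[:, None, :] >= P[None, :, :]).all(axis=2)
    gt = (P[:, None, :] > P[None, :, :]).any(axis=2)
    dominated = (ge & gt).any(axis=0)  # dominated[j]: some i beats j
    return np.nonzero(~dominated)[0]


def _staircase(points: np.ndarray, ref: np.ndarray):
    """Maximal staircase of the region dominated by ``points`` above ``ref``.

    Returns (xa, ya): breakpoint x ascending with strictly descending y, only
    points strictly above ref in both coordinates. Empty arrays when nothing
    dominates ref.
    """
    P = np.atleast_2d(points)
    keep = (P[:, 0] > ref[0]) & (P[:, 1] > ref[1])
    P = P[keep]
    if len(P) == 0:
        return np.empty(0), np.empty(0)
    nd = P[pareto_front(P)]
    # drop exact duplicates, sort x ascending (y then strictly descending)
    nd = np.unique(nd, axis=0)
    order = np.argsort(nd[:, 0])
    return nd[order, 0], nd[order, 1]


def _hv_from_staircase(xa: np.ndarray, ya: np.ndarray, ref: np.ndarray) -> float:
    if len(xa) == 0:
        return 0.0
    # sweep x descending: widths between consecutive breakpoints times height
    hv = 0.0
    prev_y = ref[1]
    for x, y in zip(xa[::-1], ya[::-1]):  # x descending, y ascending
        hv += (x - ref[0]) * (y - prev_y)
        prev_y = y
    return float(hv)


def hypervolume_2d(front: np.ndarray, ref: np.ndarray) -> float:
    """Exact area dominated by ``front`` relative to ``ref`` (maximize-all).

    Every front point must dominate the reference point.
    """
    F = np.atleast_2d(np.asarray(front, float))
    ref = np.asarray(ref, float)
    for p in F:
        if not (np.all(p >= ref) and np.any(p > ref)):
            raise ValueError(f"front point {p} does not dominate the reference {ref}")
    xa, ya = _staircase(F, ref)
    return _hv_from_staircase(xa, ya, ref)


def _contributions(xa, ya, ref, cand: np.ndarray) -> np.ndarray:
    """Hypervolume each candidate point adds to the staircase (vectorized).

    ``cand`` is (k, 2); returns (k,) of non-negative areas. Candidates not
    dominating ref contribute exactly 0.
    """
    px = cand[:, 0]
    py = cand[:, 1]
    # segment edges along x: ref_x | xa[0] | xa[1] ... | +inf, with the
    # staircase height on each segment (ya descending along ascending xa)
    seg_lo = np.concatenate(([ref[0]], xa))
    seg_hi = np.concatenate((xa, [np.inf]))
    heights = np.concatenate((ya, [ref[1]])) if len(xa) else np.array([ref[1]])
    if len(xa) == 0:
        seg_lo, seg_hi = np.array([ref[0]]), np.array([np.inf])
    widths = np.clip(np.minimum(seg_hi[None, :], px[:, None]) - seg_lo[None, :], 0.0, None)
    gains = np.clip(py[:, None] - np.maximum(heights[None, :], ref[1]), 0.0, None)
    return (widths * gains).sum(axis=1)


def nehvi(
    candidates: np.ndarray,
    gp: GPSurrogate,
    observed_X: np.ndarray,
    ref: np.ndarray,
    n_mc: int = 128,
    seed: int = 0,
) -> np.ndarray:
    """Noisy expected hypervolume improvement of each candidate embedding.

    For each of ``n_mc`` Monte-Carlo draws the GP posterior is sampled
    jointly at ``observed_X`` and at all candidates; the draw's sampled
    observed values form a "noiseless" Pareto front, and a candidate is
    credited with ``HV(front ∪ {candidate sample}) - HV(front)``. The
    returned per-candidate values are means over draws, non-negative by
    construction, and deterministic for a fixed seed.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    C = np.atleast_2d(np.asarray(candidates, float))
    O = np.atleast_2d(np.asarray(observed_X, float))
    ref = np.asarray(ref, float)
    for m in gp.models:
        if not m._fitted:
            raise RuntimeError("GP surrogate is not fitted")
    rng = np.random.default_rng(seed)
    samples = gp.sample(np.vstack([O, C]), n_mc, rng)  # (n_mc, m+k, 2)
    m = len(O)
    acq = np.zeros(len(C))
    for t in range(n_mc):
        xa, ya = _staircase(samples[t, :m, :], ref)
        acq += _contributions(xa, ya, ref, samples[t, m:, :])
    return acq / n_mc
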