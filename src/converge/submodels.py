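"""Empirical amino-acid substitution models (Dayhoff, WAG) with +G/+I.

A model is a reversible 20-state continuous-time Markov chain assembled from a
symmetric exchangeability matrix ``S`` and equilibrium frequencies ``pi``:

    Q_ij = S_ij * pi_j   (i != j),      Q_ii = -sum_{j != i} Q_ij,

rescaled so the expected substitution rate at equilibrium,
``-sum_i pi_i Q_ii``, equals 1 — branch lengths are then expected
substitutions per site under every model.  Among-site rate variation uses the
discrete-gamma approximation (k equal-weight categories at their category
means) optionally combined with a proportion ``p_inv`` of invariant sites.

The bundled exchangeabilities and frequencies are the published Dayhoff and
WAG matrices, shipped as plain-text data files (lower triangle in the
canonical ARNDCQEGHILKMFPSTWYV residue order, then the 20 frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .seqio import AA_ORDER

N_STATES = 20

_MODEL_FILES = {"DAYHOFF": "dayhoff.txt", "WAG": "wag.txt"}


class ModelError(ValueError):
    """Invalid substitution-model parameters or data."""


@dataclass
class SubstitutionModel:
    """A reversible amino-acid model plus rate-heterogeneity settings.

    Parameters
    ----------
    name : str
        Model label, e.g. ``"WAG"`` or ``"DAYHOFF"``.
    S : (20, 20) ndarray
        Symmetric exchangeabilities; the diagonal is ignored.
    pi : (20,) ndarray
        Equilibrium frequencies, strictly positive, summing to 1.
    alpha : float or None
        Gamma shape for among-site rate variation; ``None`` disables +G.
    k : int
        Number of discrete gamma categories (>= 1).
    p_inv : float
        Proportion of invariant sites in [0, 1).
    """

    name: str
    S: np.ndarray
    pi: np.ndarray
    alpha: float | None = None
    k: int = 4
    p_inv: float = 0.0
    _spectral: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.S.shape != (N_STATES, N_STATES):
            raise ModelError(f"S must be 20x20, got {self.S.shape}")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ModelError("exchangeability matrix S must be symmetric")
        if np.any(self.S[~np.eye(N_STATES, dtype=bool)] < 0):
            raise ModelError("off-diagonal exchangeabilities must be >= 0")
        if self.pi.shape != (N_STATES,):
            raise ModelError("pi must have 20 entries")
        if np.any(self.pi <= 0):
            raise ModelError("all equilibrium frequencies must be positive")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ModelError(f"frequencies sum to {self.pi.sum():.10f}, not 1")
        self.pi = self.pi / self.pi.sum()
        if self.alpha is not None and self.alpha <= 0:
            raise ModelError("gamma shape alpha must be > 0")
        if self.k < 1:
            raise ModelError("number of gamma categories k must be >= 1")
        if not 0.0 <= self.p_inv < 1.0:
            raise ModelError("p_inv must lie in [0, 1)")

    @property
    def Q(self) -> np.ndarray:
        return build_rate_matrix(self)

    def rates_and_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Gamma-category (rate, weight) arrays, excluding the invariant class."""
        pairs = discrete_gamma_rates(self.alpha, self.k, self.p_inv)
        variable = [(r, w) for r, w in pairs if r > 0.0]
        rates = np.array([r for r, _ in variable])
        weights = np.array([w for _, w in variable])
        return rates, weights

    def spectral(self):
        """Cached symmetric eigendecomposition of Q for fast P(t).

        Returns ``(evals, left, right)`` with
        ``P(t) = left @ diag(exp(evals*t)) @ right``.
        """
        if self._spectral is None:
            Q = build_rate_matrix(self)
            sq = np.sqrt(self.pi)
            B = (Q * sq[:, None]) / sq[None, :]
            B = 0.5 * (B + B.T)  # enforce exact symmetry
            evals, U = np.linalg.eigh(B)
            left = U / sq[:, None]
            right = U.T * sq[None, :]
            self._spectral = (evals, left, right)
        return self._spectral

    def with_frequencies(self, pi: np.ndarray) -> "SubstitutionModel":
        """Same exchangeabilities with replaced frequencies (+F variants)."""
        return SubstitutionModel(
            self.name + "+F", self.S, pi, alpha=self.alpha, k=self.k, p_inv=self.p_inv
        )

    def describe(self) -> str:
        parts = [self.name]
        if self.alpha is not None:
            parts.append(f"G{self.k}(alpha={self.alpha:g})")
        if self.p_inv > 0:
            parts.append(f"I(p={self.p_inv:g})")
        return "+".join(parts)


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Normalized reversible rate matrix Q from S and pi.

    Zero row sums; mean rate ``-sum_i pi_i Q_ii`` rescaled to exactly 1, so a
    branch of length t accumulates t expected substitutions per site.
    """
    Q = model.S * model.pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.dot(model.pi, np.diag(Q))
    if mean_rate <= 0:
        raise ModelError("degenerate model: zero mean substitution rate")
    return Q / mean_rate


def transition_probabilities(
    Q: np.ndarray, t: float, pi: np.ndarray | None = None
) -> np.ndarray:
    """P(t) = expm(Q t) for a reversible Q, via symmetric eigendecomposition.

    ``pi`` may be omitted, in which case the stationary distribution is
    recovered from Q's left null space.
    """
    if t < 0:
        raise ModelError(f"branch length must be >= 0, got {t}")
    Q = np.asarray(Q, dtype=float)
    if pi is None:
        evals, evecs = np.linalg.eig(Q.T)
        idx = int(np.argmin(np.abs(evals)))
        pi = np.real(evecs[:, idx])
        pi = pi / pi.sum()
    sq = np.sqrt(pi)
    B = (Q * sq[:, None]) / sq[None, :]
    B = 0.5 * (B + B.T)
    evals, U = np.linalg.eigh(B)
    P = (U / sq[:, None]) * np.exp(evals * t) @ (U.T * sq[None, :])
    return np.maximum(P, 0.0)


def discrete_gamma_rates(
    alpha: float | None, k: int, p_inv: float = 0.0
) -> list[tuple[float, float]]:
    """Discrete-gamma (+I) rate categories as (rate, weight) pairs.

    k equal-weight categories take the category means of Gamma(alpha, alpha)
    (mean 1), each scaled by 1/(1 - p_inv); when ``p_inv > 0`` an extra
    invariant category (rate 0, weight p_inv) is appended.  The weighted mean
    rate is exactly 1.
    """
    if k < 1:
        raise ModelError("k must be >= 1")
    if not 0.0 <= p_inv < 1.0:
        raise ModelError("p_inv must lie in [0, 1)")
    if alpha is None or k == 1:
        cats = [(1.0 / (1.0 - p_inv), 1.0 - p_inv)]
    else:
        if alpha <= 0:
            raise ModelError("alpha must be > 0")
        # Category boundaries at quantiles i/k of Gamma(alpha, rate alpha);
        # category mean of a Gamma via the incomplete-gamma identity
        # E[X; a<X<b] = F_{alpha+1}(b) - F_{alpha+1}(a) for mean-1 scaling.
        bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
        upper = gammainc(alpha + 1.0, np.append(bounds * alpha, np.inf))
        lower = gammainc(alpha + 1.0, np.insert(bounds * alpha, 0, 0.0))
        means = k * (upper - lower)
        means = means / np.dot(means, np.full(k, 1.0 / k))  # exact mean 1
        cats = [(m / (1.0 - p_inv), (1.0 - p_inv) / k) for m in means]
    if p_inv > 0.0:
        cats.append((0.0, p_inv))
    return cats


def _load_model_data(name: str) -> tuple[np.ndarray, np.ndarray]:
    fname = _MODEL_FILES[name]
    text = resources.files("converge.data").joinpath(fname).read_text()
    rows = [
        [float(x) for x in ln.split()]
        for ln in text.splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if len(rows) != 20 or [len(r) for r in rows[:-1]] != list(range(1, 20)):
        raise ModelError(f"corrupt model data file {fname}")
    S = np.zeros((N_STATES, N_STATES))
    for i, vals in enumerate(rows[:-1], start=1):
        S[i, :i] = vals
    S = S + S.T
    pi = np.array(rows[-1])
    return S, pi / pi.sum()


def load_model(
    name: str,
    alpha: float | None = None,
    k: int = 4,
    p_inv: float = 0.0,
    frequencies: np.ndarray | None = None,
) -> SubstitutionModel:
    """Load a bundled model by name ("WAG" or "DAYHOFF").

    ``frequencies`` replaces the model's equilibrium frequencies (the +F
    option, e.g. empirical alignment frequencies).
    """
    key = name.upper()
    if key not in _MODEL_FILES:
        raise ModelError(f"unknown model {name!r}; available: {sorted(_MODEL_FILES)}")
    S, pi = _load_model_data(key)
    if frequencies is not None:
        pi = np.asarray(frequencies, dtype=float)
        key += "+F"
    return SubstitutionModel(key, S, pi, alpha=alpha, k=k, p_inv=p_inv)


def empirical_frequencies(aln, pseudocount: float = 0.5) -> np.ndarray:
    """Observed residue frequencies of an alignment (missing data ignored).

    A small pseudocount keeps absent residues at a positive frequency, as a
    zero frequency is inadmissible in a reversible model.
    """
    codes = aln.codes
    counts = np.bincount(codes[codes < N_STATES].ravel(), minlength=N_STATES)
    freqs = counts + pseudocount
    return freqs / freqs.sum()


__all__ = [
    "AA_ORDER",
    "N_STATES",
    "SubstitutionModel",
    "ModelError",
    "build_rate_matrix",
    "transition_probabilities",
    "discrete_gamma_rates",
    "load_model",
    "empirical_frequencies",
]
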