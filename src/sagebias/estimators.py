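"""Deterministic estimators and densities for bias-corrected tag counts.

The observed tag-count vector ``t = (t_1, ..., t_l)`` is multinomial over the
*tag pool* proportions ``theta``, which are a biased image of the mRNA
population proportions ``m``:

    theta_i = m_i * phi_i / sum_j m_j * phi_j

where ``phi_i`` is the known tag-formation probability of gene ``i``. This
module provides the bias map, the corrected maximum-likelihood estimator
(``m_hat_i`` proportional to ``t_i / phi_i``), the unnormalized log posterior
under a Dirichlet(alpha) prior, and the closed-form quantities of the
missing-data (MD) augmented-Dirichlet model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

SIMPLEX_ATOL = 1e-9  # tolerance for membership of the probability simplex

__all__ = [
    "TagLibrary",
    "SIMPLEX_ATOL",
    "observed_proportions",
    "biased_from_true",
    "corrected_mle",
    "log_posterior",
    "md_posterior_mode",
    "md_marginal_mean",
]


@dataclass
class TagLibrary:
    """Per-gene aggregated tag counts with known tag-formation probabilities.

    Attributes
    ----------
    gene_ids : list of str
        Unique gene identifiers, aligned with ``t`` and ``phi``.
    t : ndarray of int
        Aggregated observed tag counts (>= 0). Zero-count genes are retained:
        absence of a tag is informative under the corrected model.
    phi : ndarray of float
        Tag-formation probabilities in (0, 1]; genes with phi = 0 are
        unobservable and must be excluded before constructing the library.
    """

    gene_ids: list[str]
    t: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t)
        self.phi = np.asarray(self.phi, dtype=float)
        if len(self.gene_ids) == 0:
            raise ValueError("empty library")
        if not (len(self.gene_ids) == self.t.shape[0] == self.phi.shape[0]):
            raise ValueError("gene_ids, t and phi must have equal length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = {g for g in self.gene_ids if self.gene_ids.count(g) > 1}
            raise ValueError(f"duplicate gene_id(s): {sorted(dupes)}")
        if np.any(self.t < 0):
            raise ValueError("negative tag counts")
        if not np.all(np.equal(np.mod(self.t, 1), 0)):
            raise ValueError("tag counts must be integers")
        self.t = self.t.astype(np.int64)
        if np.any(self.phi <= 0.0) or np.any(self.phi > 1.0):
            raise ValueError("phi values must lie in (0, 1]")

    @property
    def l(self) -> int:  # noqa: E743 - the field's standard symbol
        return len(self.gene_ids)

    @property
    def t_tot(self) -> int:
        return int(self.t.sum())


def _check_simplex(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("proportions must be nonnegative")
    if abs(m.sum() - 1.0) > SIMPLEX_ATOL:
        raise ValueError(f"proportions must sum to 1 (got {m.sum()!r})")
    return m


def observed_proportions(lib: TagLibrary) -> np.ndarray:
    """Naive (uncorrected) sample proportions ``t_i / t_tot``."""
    if lib.t_tot <= 0:
        raise ValueError("library has no observed tags")
    return lib.t / lib.t_tot


def biased_from_true(m: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Map true mRNA proportions to tag-pool proportions:
    ``theta_i = m_i phi_i / sum_j m_j phi_j``."""
    m = _check_simplex(m)
    phi = np.asarray(phi, dtype=float)
    if m.shape != phi.shape:
        raise ValueError("m and phi must have matching shapes")
    w = m * phi
    s = w.sum()
    if s <= 0:
        raise ValueError("sum of m_i * phi_i is zero; no observable mass")
    return w / s


def corrected_mle(lib: TagLibrary) -> np.ndarray:
    """Bias-corrected maximum-likelihood estimate of the mRNA proportions.

    The estimate is the unique simplex point with ``m_hat_i`` proportional to
    ``t_i / phi_i``; pushing it back through the bias map reproduces the
    observed proportions exactly, which is the estimating equation the MLE
    must satisfy. Zero-count genes receive exactly 0.
    """
    if lib.t_tot <= 0:
        raise ValueError("library has no observed tags")
    raw = lib.t / lib.phi
    return raw / raw.sum()


def log_posterior(m: np.ndarray, lib: TagLibrary, alpha: np.ndarray) -> float:
    """Unnormalized log posterior density of ``m`` (natural log).

    Equals the bias-corrected multinomial log likelihood plus the
    Dirichlet(alpha) log prior, dropping constants:

        sum_i [ t_i log(m_i phi_i) + (alpha_i - 1) log m_i ]
        - t_tot log( sum_j m_j phi_j )

    Boundary behaviour: a coordinate with ``m_i = 0`` contributes -inf when
    its density exponent ``t_i + alpha_i - 1`` is positive (density vanishes)
    and +inf when the exponent is negative (density diverges); either is
    returned as the corresponding infinity rather than raising.
    """
    m = _check_simplex(m)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), m.shape)
    if m.shape[0] != lib.l:
        raise ValueError("dimension mismatch between m and library")
    expo = lib.t + alpha - 1.0
    zero = m == 0.0
    if np.any(zero):
        if np.any(expo[zero] < 0):
            return float("inf")
        if np.any(expo[zero] > 0):
            return float("-inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        logm = np.where(zero, 0.0, np.log(np.where(zero, 1.0, m)))
    s = float(np.sum(m * lib.phi))
    if s <= 0:
        return float("-inf")
    val = np.sum(lib.t * (logm + np.log(lib.phi))) + np.sum((alpha - 1.0) * logm)
    return float(val - lib.t_tot * np.log(s))


def md_posterior_mode(t: np.ndarray, alpha: np.ndarray, r: int) -> np.ndarray:
    """Mode of the MD model's augmented-Dirichlet conditional for ``m``:

        (t_i + alpha_i - 1) / ( sum_j (alpha_j + t_j) + r - l )

    Only defined when ``t_i + alpha_i >= 1`` for every gene; with a sub-unit
    prior weight (e.g. alpha_i = 1/l) on a zero-count gene the formal mode
    leaves the parameter space.
    """
    t = np.asarray(t, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), t.shape)
    if r < 0:
        raise ValueError("unconverted count r must be >= 0")
    if np.any(t + alpha < 1.0):
        bad = np.flatnonzero(t + alpha < 1.0)
        raise ValueError(
            f"mode undefined: t_i + alpha_i < 1 at indices {bad.tolist()}; "
            "this leads to estimates outside of the parameter space"
        )
    denom = np.sum(alpha + t) + r - t.shape[0]
    return (t + alpha - 1.0) / denom


def md_marginal_mean(t: np.ndarray, alpha: np.ndarray, mu: float) -> np.ndarray:
    """Marginal posterior expectation of the augmented-model coordinate of
    ``m_i``, averaging the conditional mean

        E[m_i | r] = (t_i + alpha_i) / ( sum_j (t_j + alpha_j) + r + 1 )

    over ``r ~ Poisson(mu)``. The Poisson mass is exhausted numerically to a
    cumulative tail below 1e-12.
    """
    t = np.asarray(t, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), t.shape)
    if mu < 0:
        raise ValueError("Poisson mean mu must be >= 0")
    num = t + alpha
    total = num.sum()
    if mu == 0.0:
        return num / (total + 1.0)
    r_hi = int(stats.poisson.ppf(1.0 - 1e-13, mu)) + 2
    r = np.arange(r_hi + 1)
    w = stats.poisson.pmf(r, mu)
    scale = np.sum(w / (total + r + 1.0))
    return num * scale
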