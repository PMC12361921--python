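"""Time-reversible nucleotide substitution models.

Implements the JC / K80 / HKY / GTR family with optional discrete-gamma
rate heterogeneity (equal-probability categories, category means computed
from the incomplete gamma function) and AIC-based model selection on a
fixed topology.

Conventions
-----------
* State order is A, C, G, T.
* Exchangeabilities are ordered AC, AG, AT, CG, CT, GT with GT fixed to 1
  when free parameters are counted.
* The rate matrix Q is always rescaled so a branch length of 1 equals one
  expected substitution per site at stationarity.
* Free-parameter counts used for AIC (branch lengths excluded because all
  candidates share the same fixed branch set): JC 0; K80 1 (kappa);
  HKY 4 (kappa + 3 frequencies); GTR 8 (5 exchangeabilities + 3
  frequencies); +G adds 1 (gamma shape).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

MODEL_NAMES = ("JC", "K80", "HKY", "GTR")
_EXCH_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

_K_FREE = {"JC": 0, "K80": 1, "HKY": 4, "GTR": 8}


class ModelError(ValueError):
    pass


def discrete_gamma(alpha: float, K: int) -> np.ndarray:
    """Mean rates of K equal-probability categories of Gamma(alpha, alpha).

    Uses the standard mean-per-quantile discretization: category i's rate is
    the conditional mean of a mean-1 gamma variate between the i/K and
    (i+1)/K quantiles, so the category means average exactly to 1.
    """
    if alpha <= 0:
        raise ModelError("gamma shape must be positive")
    if K < 1:
        raise ModelError("need at least one rate category")
    if K == 1:
        return np.ones(1)
    # Quantile boundaries of Gamma(shape=alpha, rate=alpha).
    probs = np.arange(1, K) / K
    bounds = gamma_dist.ppf(probs, alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # E[X; X<=b] for mean-1 gamma = P(Gamma(alpha+1, alpha) <= b).
    upper = np.where(np.isinf(bounds), 1.0, gammainc(alpha + 1.0, alpha * bounds))
    rates = K * np.diff(upper)
    return rates / rates.mean()  # exact mean 1 against roundoff


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible CTMC on {A,C,G,T}, optionally with +Gamma rates."""

    name: str
    exchangeabilities: tuple[float, ...]  # AC, AG, AT, CG, CT, GT
    base_freqs: tuple[float, float, float, float]
    gamma_shape: Optional[float] = None
    n_rate_categories: int = 1

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ModelError(f"unknown model {self.name!r}")
        freqs = np.asarray(self.base_freqs, float)
        if freqs.min() <= 0 or abs(freqs.sum() - 1.0) > 1e-12:
            raise ModelError("base frequencies must be positive and sum to 1")
        if len(self.exchangeabilities) != 6 or min(self.exchangeabilities) < 0:
            raise ModelError("need 6 non-negative exchangeabilities")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ModelError("gamma shape must be positive")
        if self.gamma_shape is None and self.n_rate_categories != 1:
            raise ModelError("rate categories require a gamma shape")

    # -------------------------------------------------------- constructors

    @classmethod
    def jc(cls, gamma_shape=None, n_rate_categories=4) -> "SubstitutionModel":
        return cls(
            "JC", (1.0,) * 6, (0.25,) * 4,
            gamma_shape, n_rate_categories if gamma_shape else 1,
        )

    @classmethod
    def k80(cls, kappa: float, gamma_shape=None, n_rate_categories=4):
        ex = (1.0, kappa, 1.0, 1.0, kappa, 1.0)
        return cls(
            "K80", ex, (0.25,) * 4,
            gamma_shape, n_rate_categories if gamma_shape else 1,
        )

    @classmethod
    def hky(cls, kappa: float, freqs, gamma_shape=None, n_rate_categories=4):
        ex = (1.0, kappa, 1.0, 1.0, kappa, 1.0)
        return cls(
            "HKY", ex, tuple(float(f) for f in freqs),
            gamma_shape, n_rate_categories if gamma_shape else 1,
        )

    @classmethod
    def gtr(cls, exchangeabilities, freqs, gamma_shape=None, n_rate_categories=4):
        return cls(
            "GTR",
            tuple(float(x) for x in exchangeabilities),
            tuple(float(f) for f in freqs),
            gamma_shape, n_rate_categories if gamma_shape else 1,
        )

    # ------------------------------------------------------------- matrices

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.base_freqs, float)

    def rate_matrix(self) -> np.ndarray:
        """Q scaled to one expected substitution per site per unit length."""
        pi = self.pi
        Q = np.zeros((4, 4))
        for rate, (i, j) in zip(self.exchangeabilities, _EXCH_PAIRS):
            Q[i, j] = rate * pi[j]
            Q[j, i] = rate * pi[i]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def eigensystem(self):
        """Symmetric decomposition of Q for fast matrix exponentials.

        Returns (eigenvalues, U, U_inv) with Q = U diag(w) U_inv.
        """
        pi = self.pi
        sqrt_pi = np.sqrt(pi)
        Q = self.rate_matrix()
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        w, V = eigh((B + B.T) / 2.0)
        U = V / sqrt_pi[:, None]
        U_inv = V.T * sqrt_pi[None, :]
        return w, U, U_inv

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma(self.gamma_shape, self.n_rate_categories)

    @property
    def display_name(self) -> str:
        return self.name + (
            f"+G{self.n_rate_categories}" if self.gamma_shape is not None else ""
        )

    def k_free_parameters(self) -> int:
        return _K_FREE[self.name] + (1 if self.gamma_shape is not None else 0)


def transition_matrix(
    model: SubstitutionModel, t: float, rate: float = 1.0
) -> np.ndarray:
    """P(t) = exp(Q * t * rate); rows sum to 1."""
    if t < 0:
        raise ModelError("branch length must be non-negative")
    if rate <= 0:
        raise ModelError("rate multiplier must be positive")
    w, U, U_inv = model.eigensystem()
    P = (U * np.exp(w * t * rate)) @ U_inv
    np.clip(P, 0.0, None, out=P)
    return P / P.sum(axis=1, keepdims=True)


def transition_matrices(
    eigensystem, ts: np.ndarray, rates: np.ndarray
) -> np.ndarray:
    """Stack of P(t_i * r_k): shape (len(ts), len(rates), 4, 4)."""
    w, U, U_inv = eigensystem
    scaled = np.asarray(ts, float)[:, None, None] * np.asarray(rates, float)[None, :, None]
    E = np.exp(scaled * w[None, None, :])  # (n, K, 4)
    P = (U[None, None, :, :] * E[:, :, None, :]) @ U_inv
    np.clip(P, 0.0, None, out=P)
    return P / P.sum(axis=3, keepdims=True)


@dataclass
class ModelFit:
    model: SubstitutionModel
    log_likelihood: float
    k: int
    converged: bool = True
    message: str = ""

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.log_likelihood


def empirical_frequencies(sequences: Sequence[str]) -> tuple[float, ...]:
    """Empirical A/C/G/T frequencies over unambiguous characters (+F)."""
    counts = np.ones(4)  # +1 pseudocount keeps frequencies positive
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for seq in sequences:
        for ch in seq:
            i = index.get(ch)
            if i is not None:
                counts[i] += 1
    freqs = counts / counts.sum()
    return tuple(float(f) for f in freqs)


def candidate_models(
    names: Sequence[str], freqs: tuple[float, ...]
) -> list[SubstitutionModel]:
    """Instantiate starting models for candidate strings like 'GTR+G'."""
    out = []
    for spec in names:
        base, plus, *_ = (spec.split("+") + [""])[:2]
        gamma = 0.5 if plus.startswith("G") else None
        if base == "JC":
            out.append(SubstitutionModel.jc(gamma))
        elif base == "K80":
            out.append(SubstitutionModel.k80(2.0, gamma))
        elif base == "HKY":
            out.append(SubstitutionModel.hky(2.0, freqs, gamma))
        elif base == "GTR":
            out.append(SubstitutionModel.gtr((1.0,) * 6, freqs, gamma))
        else:
            raise ModelError(f"unknown candidate {spec!r}")
    return out


def select_model(aln, tree, candidates: Sequence[str], **kwargs) -> ModelFit:
    """AIC model selection on a fixed topology (ties -> fewer parameters).

    Thin wrapper over :func:`cytodisc.inference.fit_candidates`; lives here
    so the model-selection surface sits with the model family.
    """
    from .inference import fit_candidates

    fits = fit_candidates(aln, tree, candidates, **kwargs)
    return min(fits, key=lambda f: (round(f.aic, 9), f.k))
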