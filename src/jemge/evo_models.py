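"""Closed-form evolutionary processes.

Three independent continuous-time processes act on a pair of homologous
regions:

* nucleotide substitution — an F81-type reversible process with a single
  rate ``s`` and stationary base frequencies ``pi``;
* the binary histone-mark switch — a two-state Poisson switch process with
  rate ``kappa`` per mark and stationary on-probability ``pi1``;
* insertion/deletion — the TKF91 birth-death chain with birth (insertion)
  rate ``lambda`` and death (deletion) rate ``mu``, ``lambda < mu``.

Evolutionary time ``t`` is fixed at 1 by convention (``DEFAULT_TIME``); the
rates are therefore expected numbers of events per unit branch length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Evolutionary time separating the two regions; rates absorb the branch
#: length, so this stays at 1.
DEFAULT_TIME: float = 1.0

#: Probabilities estimated by frequency counting are clamped into
#: [PROB_CLAMP, 1-PROB_CLAMP] so every log in the likelihood stays finite.
PROB_CLAMP: float = 1e-6

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class ParameterDomainError(ValueError):
    """A rate or probability is outside its valid domain."""


class InvalidSymbolError(ValueError):
    """A base or mark state outside its alphabet."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleotideDistribution:
    """Stationary base frequencies (A, C, G, T)."""

    pi_A: float = 0.25
    pi_C: float = 0.25
    pi_G: float = 0.25
    pi_T: float = 0.25

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < 0) or np.any(arr > 1):
            raise ParameterDomainError("base frequencies must lie in [0, 1]")
        if abs(float(arr.sum()) - 1.0) > 1e-12:
            raise ParameterDomainError("base frequencies must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.pi_A, self.pi_C, self.pi_G, self.pi_T], float)

    def __getitem__(self, base: str) -> float:
        try:
            return float(self.as_array()[BASE_INDEX[base]])
        except KeyError:
            raise InvalidSymbolError(f"not a nucleotide: {base!r}") from None


@dataclass(frozen=True)
class MarkParams:
    """One histone mark: global on-probability ``pi1`` and switch rate ``kappa``.

    ``index`` is the 1-based mark number (h); ``pi0`` is derived, never stored.
    """

    index: int
    pi1: float
    kappa: float

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ParameterDomainError("mark index is 1-based")
        if not (0.0 < self.pi1 < 1.0):
            raise ParameterDomainError("pi1 must lie strictly in (0, 1); clamp first")
        if self.kappa < 0:
            raise ParameterDomainError("kappa must be >= 0")

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1


@dataclass(frozen=True)
class LocalEquilibria:
    """Per-region mark equilibria: phi_A1[h], phi_B1[h], one entry per mark.

    These are mixture weights over the two switch-process start states used on
    indel columns (models N and M); 0 and 1 are legal values.
    """

    phi_A1: tuple[float, ...]
    phi_B1: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.phi_A1) != len(self.phi_B1):
            raise ValueError("phi_A1 and phi_B1 must cover the same marks")
        for v in (*self.phi_A1, *self.phi_B1):
            if not (0.0 <= v <= 1.0):
                raise ParameterDomainError("local equilibria must lie in [0, 1]")


@dataclass(frozen=True)
class IndelParams:
    """TKF91 insertion (birth) rate lambda and deletion (death) rate mu."""

    lam: float
    mu: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lam < self.mu) or not math.isfinite(self.mu):
            raise ParameterDomainError(
                f"need 0 < lambda < mu < inf, got lambda={self.lam}, mu={self.mu}"
            )


@dataclass(frozen=True)
class EvoParams:
    """All continuous parameters of the joint model."""

    nuc: NucleotideDistribution
    marks: tuple[MarkParams, ...]
    indel: IndelParams
    s: float
    t: float = DEFAULT_TIME

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ParameterDomainError("substitution rate s must be >= 0")
        if self.t <= 0:
            raise ParameterDomainError("time t must be > 0")

    @property
    def n_marks(self) -> int:
        return len(self.marks)


@dataclass(frozen=True)
class TKFQuantities:
    """Ancestral-link fate probabilities of the TKF91 model over time t.

    beta        the TKF beta(t) function
    p1          link survives with exactly one descendant
    p0_prime    link dies leaving no descendant (= mu*beta)
    p1_prime    link dies leaving exactly one descendant
    lam_beta    lambda*beta, the geometric birth ratio
    """

    beta: float
    p1: float
    p0_prime: float
    p1_prime: float
    lam_beta: float

    @property
    def one_minus_lam_beta(self) -> float:
        return 1.0 - self.lam_beta

    def p_double_prime(self, n: int) -> float:
        """Probability the immortal link spawns n-1 extra descendants (n >= 1)."""
        if n < 1:
            raise ValueError("p'' is defined for n >= 1")
        return (1.0 - self.lam_beta) * self.lam_beta ** (n - 1)


# ---------------------------------------------------------------------------
# transition kernels
# ---------------------------------------------------------------------------

def nuc_substitution_prob(a: str, b: str, s: float, t: float,
                          pi: NucleotideDistribution) -> float:
    """F81 transition probability f_{a,b}(t) = e^{-st}·1[a=b] + pi_b(1-e^{-st})."""
    if a not in BASE_INDEX or b not in BASE_INDEX:
        raise InvalidSymbolError(f"not nucleotides: {a!r}, {b!r}")
    if s < 0 or t < 0:
        raise ParameterDomainError("s and t must be >= 0")
    decay = math.exp(-s * t)
    return decay * (a == b) + pi[b] * (1.0 - decay)


def epi_switch_prob(x: int, y: int, kappa: float, t: float, pi1: float) -> float:
    """Two-state switch kernel g_{x,y}(t) = e^{-kt}·1[x=y] + pi_y(1-e^{-kt})."""
    if x not in (0, 1) or y not in (0, 1):
        raise InvalidSymbolError(f"mark states must be 0/1, got {x!r}, {y!r}")
    if kappa < 0 or t < 0:
        raise ParameterDomainError("kappa and t must be >= 0")
    decay = math.exp(-kappa * t)
    pi_y = pi1 if y == 1 else 1.0 - pi1
    return decay * (x == y) + pi_y * (1.0 - decay)


def phi_marginal(y: int, phi1: float, kappa: float, t: float, pi1: float) -> float:
    """Mark distribution on an indel column: Phi(y) = (1-phi1)·g_{0,y} + phi1·g_{1,y}.

    Used for a descendant position inserted into region B (with phi1 = phi_A1)
    or, by reversibility, an ancestral position deleted from region A (with
    phi1 = phi_B1).
    """
    if not (0.0 <= phi1 <= 1.0):
        raise ParameterDomainError("phi1 must lie in [0, 1]")
    return ((1.0 - phi1) * epi_switch_prob(0, y, kappa, t, pi1)
            + phi1 * epi_switch_prob(1, y, kappa, t, pi1))


def tkf_quantities(lam: float, mu: float, t: float) -> TKFQuantities:
    """Evaluate the TKF91 closed forms beta, p1, p0', p1' at time t.

    beta(t) = (1 - e^{(lam-mu)t}) / (mu - lam·e^{(lam-mu)t})
    p1      = e^{-mu t} (1 - lam·beta)
    p0'     = mu·beta
    p1'     = (1 - e^{-mu t} - mu·beta)(1 - lam·beta)
    """
    if lam < 0 or mu < 0:
        raise ParameterDomainError("rates must be >= 0")
    if lam >= mu:
        raise ParameterDomainError("TKF91 requires lambda < mu")
    if t < 0:
        raise ParameterDomainError("t must be >= 0")
    if t == 0.0:
        return TKFQuantities(beta=0.0, p1=1.0, p0_prime=0.0, p1_prime=0.0,
                             lam_beta=0.0)
    growth = math.exp((lam - mu) * t)
    beta = (1.0 - growth) / (mu - lam * growth)
    lam_beta = lam * beta
    p1 = math.exp(-mu * t) * (1.0 - lam_beta)
    p0_prime = mu * beta
    # fp guard: 1 - e^{-mu t} - mu*beta is a tiny positive difference
    died_with_desc = max(1.0 - math.exp(-mu * t) - p0_prime, 0.0)
    p1_prime = died_with_desc * (1.0 - lam_beta)
    return TKFQuantities(beta=beta, p1=p1, p0_prime=p0_prime,
                         p1_prime=p1_prime, lam_beta=lam_beta)


def tied_lambda(mu: float, sA: int, sB: int) -> float:
    """Insertion rate tied to mu through the observed pair lengths.

    lambda = mu (sA+sB) / (sA+sB+2), the MLE tie of the TKF91 length
    equilibrium given a pair of lengths sA, sB; always < mu.
    """
    if mu <= 0:
        raise ParameterDomainError("mu must be > 0")
    if sA < 0 or sB < 0:
        raise ParameterDomainError("lengths must be >= 0")
    if sA == 0 and sB == 0:
        raise ParameterDomainError("degenerate pair: sA = sB = 0")
    total = sA + sB
    return mu * total / (total + 2.0)


def clamp_probability(p: float, eps: float = PROB_CLAMP) -> float:
    """Clamp a frequency estimate into [eps, 1-eps] to keep logs finite."""
    return min(max(p, eps), 1.0 - eps)
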