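"""Parameter estimation: frequency estimates, simplex MLE, and the EM mixture.

Equilibrium probabilities are estimated by frequency counting (global base
frequencies and mark on-fractions pooled over the dataset; local mark
equilibria per region).  The free continuous parameters

    theta = (mu, s, kappa_1..kappa_H)

are estimated by Nelder-Mead downhill simplex on the negative log-likelihood,
optimizing in log-parameter space so positivity holds by construction.  The
insertion rate is tied per pair, lambda_i = mu (sA_i+sB_i)/(sA_i+sB_i+2), and
evolutionary time is fixed at 1.

``fit_mixture_em`` fits the four-component mixture over models {N, M, I, B}:
the E-step computes per-pair responsibilities and updates the priors, and the
M-step improves theta against the full mixture log-likelihood at fixed
priors (a generalized-EM step, accepted only when it does not decrease the
objective), so the observed-data log-likelihood is non-decreasing.
"""

from __future__ import annotations

import dataclasses
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .evo_models import (
    EvoParams,
    IndelParams,
    LocalEquilibria,
    MarkParams,
    NucleotideDistribution,
    clamp_probability,
    epi_switch_prob,
    tied_lambda,
    tkf_quantities,
)
from .likelihood import (
    HomologousPair,
    ModelKind,
    _dp_kernel,
    encode_sequence,
    pair_log_likelihood,
)

ALL_MODELS = (ModelKind.N, ModelKind.M, ModelKind.I, ModelKind.B)

#: The two documented default simplex starting points (mu, s, kappa).
DEFAULT_INITS = ((0.02, 0.05, 0.5), (0.08, 0.1, 1.0))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dataset:
    """Homologous pairs plus the shared frequency estimates of equilibria."""

    pairs: tuple[HomologousPair, ...]
    nuc: NucleotideDistribution
    pi1: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("dataset must contain at least one pair")
        H = self.pairs[0].n_marks
        if any(p.n_marks != H for p in self.pairs):
            raise ValueError("all pairs must carry the same number of marks")
        if len(self.pi1) != H:
            raise ValueError("pi1 must have one entry per mark")

    @property
    def n_marks(self) -> int:
        return len(self.pi1)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ThetaFree:
    """The free parameters: deletion rate mu, substitution rate s, switch
    rates kappa (one per mark)."""

    mu: float
    s: float
    kappa: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.s <= 0 or any(k <= 0 for k in self.kappa):
            raise ValueError("all free parameters must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.s, *self.kappa], float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ThetaFree":
        return cls(mu=float(arr[0]), s=float(arr[1]),
                   kappa=tuple(float(v) for v in arr[2:]))


@dataclass
class FitResult:
    """Outcome of a single-model simplex MLE run."""

    model: ModelKind
    theta_hat: ThetaFree
    nll: float
    nll_trace: list[float]
    converged: bool
    n_iter: int
    theta_init: ThetaFree


@dataclass
class MixtureFit:
    """Outcome of the four-component EM mixture fit."""

    alpha: dict[ModelKind, float]
    theta_hat: ThetaFree
    gamma: np.ndarray  # (n_pairs, 4) responsibilities, model order N,M,I,B
    loglik_trace: list[float]
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# frequency estimates
# ---------------------------------------------------------------------------

def estimate_global_equilibria(
        pairs: tuple[HomologousPair, ...] | list[HomologousPair],
) -> tuple[NucleotideDistribution, tuple[float, ...]]:
    """Pooled base frequencies and per-mark on-fractions over both species."""
    if not pairs:
        raise ValueError("empty dataset")
    counts = np.zeros(4)
    H = pairs[0].n_marks
    ones = np.zeros(H)
    total = 0
    for p in pairs:
        for code in (encode_sequence(p.seqA), encode_sequence(p.seqB)):
            counts += np.bincount(code, minlength=4)
        for side in ("A", "B"):
            mm = p.marks_matrix(side)
            if H:
                ones += mm.sum(axis=1)
        total += p.sA + p.sB
    freqs = counts / counts.sum()
    freqs = np.array([clamp_probability(f) for f in freqs])
    freqs = freqs / freqs.sum()
    nuc = NucleotideDistribution(*freqs)
    pi1 = tuple(clamp_probability(float(o) / total) for o in ones)
    return nuc, pi1


def estimate_local_equilibria(pair: HomologousPair) -> LocalEquilibria:
    """Per-region mark on-fractions; 0 and 1 are legal (mixture weights)."""
    mA = pair.marks_matrix("A")
    mB = pair.marks_matrix("B")
    return LocalEquilibria(
        phi_A1=tuple(float(v) for v in mA.mean(axis=1)) if len(mA) else (),
        phi_B1=tuple(float(v) for v in mB.mean(axis=1)) if len(mB) else (),
    )


def build_dataset(pairs: list[HomologousPair] | tuple[HomologousPair, ...]
                  ) -> Dataset:
    """Attach frequency-estimated global and local equilibria to the pairs."""
    nuc, pi1 = estimate_global_equilibria(pairs)
    with_phi = tuple(
        dataclasses.replace(p, phi=estimate_local_equilibria(p)) for p in pairs)
    return Dataset(pairs=with_phi, nuc=nuc, pi1=pi1)


def params_for_pair(dataset: Dataset, pair: HomologousPair,
                    theta: ThetaFree) -> EvoParams:
    """Assemble full model parameters for one pair, with the tied lambda."""
    lam = tied_lambda(theta.mu, pair.sA, pair.sB)
    marks = tuple(MarkParams(h + 1, dataset.pi1[h], theta.kappa[h])
                  for h in range(dataset.n_marks))
    return EvoParams(nuc=dataset.nuc, marks=marks,
                     indel=IndelParams(lam, theta.mu), s=theta.s)


# ---------------------------------------------------------------------------
# fast dataset likelihood engine
# ---------------------------------------------------------------------------

class _CompiledPair:
    """Per-pair arrays and theta-independent constants, computed once."""

    __slots__ = ("acode", "bcode", "amarks", "bmarks", "pib", "ratio",
                 "phi_A1", "phi_B1", "anc_seq_base", "anc_marks", "sA", "sB")

    def __init__(self, pair: HomologousPair, nuc: NucleotideDistribution,
                 pi1: tuple[float, ...]):
        self.acode = encode_sequence(pair.seqA)
        self.bcode = encode_sequence(pair.seqB)
        self.amarks = pair.marks_matrix("A")
        self.bmarks = pair.marks_matrix("B")
        nuc_arr = nuc.as_array()
        self.pib = nuc_arr[self.bcode]
        self.sA, self.sB = pair.sA, pair.sB
        self.ratio = (self.sA + self.sB) / (self.sA + self.sB + 2.0)
        if pair.phi is None:
            raise ValueError(f"{pair.identifier}: local equilibria missing; "
                             "build the dataset with build_dataset()")
        self.phi_A1 = np.asarray(pair.phi.phi_A1, float)
        self.phi_B1 = np.asarray(pair.phi.phi_B1, float)
        # ancestor log-probability pieces (constant during optimization:
        # lambda/mu is fixed by the length tie)
        self.anc_seq_base = (math.log1p(-self.ratio)
                             + self.sA * math.log(self.ratio)
                             + float(np.log(nuc_arr[self.acode]).sum()))
        anc_marks = 0.0
        for h, p1 in enumerate(pi1):
            n_on = int(self.amarks[h].sum()) if len(self.amarks) else 0
            anc_marks += n_on * math.log(p1) + (self.sA - n_on) * math.log(1 - p1)
        self.anc_marks = anc_marks


class DatasetLikelihood:
    """Evaluates per-pair log-likelihoods for a fixed dataset, many thetas.

    Equilibria (pi, pi^h, phi) are frozen at their frequency estimates; only
    theta varies between calls.  ``threads`` > 1 distributes pairs over a
    thread pool (the DP kernel releases the GIL); the reduction order is
    fixed, so results do not depend on the thread count.
    """

    def __init__(self, dataset: Dataset, threads: int = 1):
        self.dataset = dataset
        self.H = dataset.n_marks
        self.pi1 = np.asarray(dataset.pi1, float)
        self.compiled = [
            _CompiledPair(p, dataset.nuc, dataset.pi1) for p in dataset.pairs]
        self.threads = max(1, int(threads))
        self._pool = (ThreadPoolExecutor(max_workers=self.threads)
                      if self.threads > 1 else None)

    def _mark_tables(self, kappa: np.ndarray):
        g = np.empty((self.H, 2, 2))
        pim = np.empty((self.H, 2))
        for h in range(self.H):
            for x in (0, 1):
                for y in (0, 1):
                    g[h, x, y] = epi_switch_prob(x, y, float(kappa[h]), 1.0,
                                                 float(self.pi1[h]))
            pim[h, 0] = 1.0 - self.pi1[h]
            pim[h, 1] = self.pi1[h]
        return g, pim

    def _one_pair(self, cp: _CompiledPair, model: ModelKind, theta: ThetaFree,
                  g: np.ndarray, pim: np.ndarray, est: float) -> float:
        mu = theta.mu
        lam = mu * cp.ratio
        q = tkf_quantities(lam, mu, 1.0)
        cdie = q.p1_prime - q.lam_beta * q.p0_prime
        if model.uses_local_equilibria:
            phiA = ((1.0 - cp.phi_A1)[:, None] * g[:, 0, :]
                    + cp.phi_A1[:, None] * g[:, 1, :])
            phiB = ((1.0 - cp.phi_B1)[:, None] * g[:, 0, :]
                    + cp.phi_B1[:, None] * g[:, 1, :])
            anc = cp.anc_seq_base
        else:
            phiA = phiB = np.ones((self.H, 2))
            anc = cp.anc_seq_base + cp.anc_marks
        dp = _dp_kernel(cp.acode, cp.bcode, cp.amarks, cp.bmarks, cp.pib, est,
                        g, pim, phiA, phiB, q.p1, q.p0_prime, q.lam_beta,
                        cdie, int(model))
        return anc + math.log(q.one_minus_lam_beta) + dp

    def pair_logliks(self, theta: ThetaFree,
                     models: tuple[ModelKind, ...] = ALL_MODELS) -> np.ndarray:
        """(n_pairs, len(models)) matrix of log-likelihoods."""
        g, pim = self._mark_tables(np.asarray(theta.kappa, float))
        est = math.exp(-theta.s)
        out = np.empty((len(self.compiled), len(models)))

        def work(i: int) -> None:
            cp = self.compiled[i]
            for j, model in enumerate(models):
                out[i, j] = self._one_pair(cp, model, theta, g, pim, est)

        if self._pool is not None:
            list(self._pool.map(work, range(len(self.compiled))))
        else:
            for i in range(len(self.compiled)):
                work(i)
        return out

    def nll(self, theta: ThetaFree, model: ModelKind) -> float:
        return float(-self.pair_logliks(theta, (model,)).sum())


def dataset_neg_log_likelihood(dataset: Dataset, model: ModelKind,
                               theta: ThetaFree, threads: int = 1) -> float:
    """Sum of per-pair negative log-likelihoods at theta (lambda tied per pair)."""
    return DatasetLikelihood(dataset, threads=threads).nll(theta, model)


# ---------------------------------------------------------------------------
# simplex MLE
# ---------------------------------------------------------------------------

def _theta_from_init(init, H: int) -> ThetaFree:
    if isinstance(init, ThetaFree):
        return init
    mu, s, kappa = init
    if isinstance(kappa, (int, float)):
        kappa = (float(kappa),) * H
    return ThetaFree(mu=float(mu), s=float(s), kappa=tuple(kappa))


def fit_mle(dataset: Dataset, model: ModelKind,
            theta_init: ThetaFree | tuple | None = None,
            *, xatol: float = 1e-6, fatol: float = 1e-8,
            max_iter: int = 2000, threads: int = 1,
            engine: DatasetLikelihood | None = None) -> FitResult:
    """Minimize the dataset NLL by Nelder-Mead over log-transformed theta.

    The trace records the best-vertex NLL after every simplex iteration and
    is non-increasing by the simplex acceptance rule.
    """
    H = dataset.n_marks
    theta0 = _theta_from_init(theta_init if theta_init is not None
                              else DEFAULT_INITS[0], H)
    eng = engine if engine is not None else DatasetLikelihood(dataset, threads)

    cache: dict[bytes, float] = {}

    def objective(logx: np.ndarray) -> float:
        key = logx.tobytes()
        if key not in cache:
            theta = ThetaFree.from_array(np.exp(logx))
            try:
                val = eng.nll(theta, model)
            except (ValueError, OverflowError):
                val = 1e12
            cache[key] = val if math.isfinite(val) else 1e12
        return cache[key]

    trace: list[float] = []

    def callback(xk: np.ndarray) -> None:
        trace.append(objective(xk))

    x0 = np.log(theta0.as_array())
    res = minimize(objective, x0, method="Nelder-Mead", callback=callback,
                   options={"xatol": xatol, "fatol": fatol,
                            "maxiter": max_iter, "adaptive": False})
    theta_hat = ThetaFree.from_array(np.exp(res.x))
    return FitResult(model=model, theta_hat=theta_hat, nll=float(res.fun),
                     nll_trace=trace, converged=bool(res.success),
                     n_iter=int(res.nit), theta_init=theta0)


def percent_error(theta_hat: ThetaFree, theta_star: ThetaFree) -> dict[str, float]:
    """e = (estimate - truth)/truth * 100, per free parameter."""
    star = theta_star.as_array()
    if np.any(star == 0):
        raise ValueError("percent error undefined for a zero true value")
    e = (theta_hat.as_array() - star) / star * 100.0
    out = {"mu": float(e[0]), "s": float(e[1])}
    for h in range(len(theta_star.kappa)):
        out[f"kappa_{h + 1}"] = float(e[2 + h])
    return out


# ---------------------------------------------------------------------------
# EM mixture
# ---------------------------------------------------------------------------

ALPHA_FLOOR = 1e-12


def fit_mixture_em(dataset: Dataset,
                   alpha_init: dict[ModelKind, float] | None = None,
                   theta_init: ThetaFree | tuple | None = None,
                   *, tol: float = 1e-8, max_iter: int = 200,
                   m_step_maxiter: int = 40, threads: int = 1) -> MixtureFit:
    """Fit the four-component mixture over {N, M, I, B} by generalized EM."""
    H = dataset.n_marks
    theta = _theta_from_init(theta_init if theta_init is not None
                             else DEFAULT_INITS[0], H)
    if alpha_init is None:
        alpha = np.full(4, 0.25)
    else:
        alpha = np.array([alpha_init[m] for m in ALL_MODELS], float)
        if np.any(alpha < 0) or abs(alpha.sum() - 1.0) > 1e-9:
            raise ValueError("alpha_init must be a distribution over the models")
    eng = DatasetLikelihood(dataset, threads)

    def observed_loglik(ll_matrix: np.ndarray, alpha_: np.ndarray) -> float:
        return float(logsumexp(ll_matrix + np.log(alpha_), axis=1).sum())

    ll = eng.pair_logliks(theta)
    current = observed_loglik(ll, alpha)
    trace = [current]
    gamma = np.full((len(dataset), 4), 0.25)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: responsibilities and prior update
        logw = ll + np.log(alpha)
        gamma = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
        alpha = gamma.mean(axis=0)
        alpha = np.maximum(alpha, ALPHA_FLOOR)
        alpha = alpha / alpha.sum()
        # generalized M-step: improve theta against the mixture objective
        log_alpha = np.log(alpha)
        cache: dict[bytes, float] = {}

        def neg_mix(logx: np.ndarray) -> float:
            key = logx.tobytes()
            if key not in cache:
                try:
                    th = ThetaFree.from_array(np.exp(logx))
                    val = -observed_loglik(eng.pair_logliks(th), alpha)
                except (ValueError, OverflowError):
                    val = 1e12
                cache[key] = val if math.isfinite(val) else 1e12
            return cache[key]

        res = minimize(neg_mix, np.log(theta.as_array()), method="Nelder-Mead",
                       options={"maxiter": m_step_maxiter, "xatol": 1e-6,
                                "fatol": 1e-8})
        candidate = ThetaFree.from_array(np.exp(res.x))
        cand_ll = eng.pair_logliks(candidate)
        cand_obj = observed_loglik(cand_ll, alpha)
        here_obj = observed_loglik(ll, alpha)
        if cand_obj >= here_obj:  # no-decrease acceptance guard
            theta, ll = candidate, cand_ll
            new = cand_obj
        else:
            new = here_obj
        trace.append(new)
        if abs(new - current) <= tol * max(1.0, abs(current)):
            converged = True
            current = new
            break
        current = new
    logw = ll + np.log(alpha)
    gamma = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    return MixtureFit(alpha={m: float(alpha[j]) for j, m in enumerate(ALL_MODELS)},
                      theta_hat=theta, gamma=gamma, loglik_trace=trace,
                      converged=converged, n_iter=it)
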