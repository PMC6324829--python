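"""Hypothesis-faithful simulation of homologous pairs.

Each simulated pair starts from an ancestral region drawn at equilibrium,
evolves its sequence through the TKF91 indel process and the F81
substitution process, and evolves its mark tracks according to the
generating hypothesis:

* matches: descendant marks from the switch kernel g (all models);
* mismatches: from g under N and I, from the global equilibrium under M
  and B;
* insertions: from the region's local equilibrium phi (N, M; phi drawn once
  per region from Beta(1.5, 1.5(1-pi1)/pi1), whose mean is pi1) or from the
  global equilibrium (I, B).

Defaults mirror the simulation study conditions: uniform base frequencies,
pi1 = 0.1, 100 pairs of 500-bp ancestors, one mark, t = 1.  The insertion
rate is tied to mu through the ancestor length L as lambda = mu·L/(L+1),
the value the per-pair MLE length tie takes at sA = sB = L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .evo_models import NucleotideDistribution, tkf_quantities
from .inference import ThetaFree
from .likelihood import AlignmentPath, HomologousPair, MarkTrack, ModelKind

BASES = np.array(list("ACGT"))

#: Declared simulation parameter grid: eight (mu, s, kappa) combinations
#: spanning true values {0.01, 0.1, 1}.
SIMULATION_GRID: dict[str, ThetaFree] = {
    "g1": ThetaFree(mu=0.1, s=0.1, kappa=(0.1,)),
    "g2": ThetaFree(mu=0.1, s=0.1, kappa=(1.0,)),
    "g3": ThetaFree(mu=0.1, s=1.0, kappa=(1.0,)),
    "g4": ThetaFree(mu=0.01, s=0.1, kappa=(1.0,)),
    "g5": ThetaFree(mu=0.1, s=0.01, kappa=(1.0,)),
    "g6": ThetaFree(mu=0.01, s=0.01, kappa=(0.1,)),
    "g7": ThetaFree(mu=0.1, s=0.1, kappa=(0.01,)),
    "g8": ThetaFree(mu=0.01, s=1.0, kappa=(0.1,)),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generating conditions for one synthetic dataset."""

    model: ModelKind
    theta: ThetaFree
    ancestor_length: int = 500
    n_pairs: int = 100
    pi_nuc: NucleotideDistribution = field(default_factory=NucleotideDistribution)
    pi1: tuple[float, ...] = (0.1,)
    t: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestor_length < 1:
            raise ValueError("ancestor_length must be >= 1")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if len(self.theta.kappa) != len(self.pi1):
            raise ValueError("theta.kappa and pi1 must have one entry per mark")

    @property
    def n_marks(self) -> int:
        return len(self.pi1)

    @property
    def lam(self) -> float:
        """Insertion rate tied to mu through the ancestor length."""
        L = self.ancestor_length
        return self.theta.mu * L / (L + 1.0)


@dataclass(frozen=True)
class SimulatedPair:
    """A simulated pair with its generating truth."""

    pair: HomologousPair
    path: AlignmentPath
    model: ModelKind
    theta: ThetaFree
    phi_truth: tuple[float, ...] | None  # per-mark phi1 (models N, M)


def sample_ancestor(length: int, pi_nuc: NucleotideDistribution,
                    pi1: tuple[float, ...],
                    rng: np.random.Generator) -> tuple[str, np.ndarray]:
    """IID equilibrium draw of an ancestral sequence and its mark states."""
    if length < 1:
        raise ValueError("length must be >= 1")
    seq = "".join(rng.choice(BASES, size=length, p=pi_nuc.as_array()))
    marks = np.stack([
        (rng.random(length) < p1).astype(np.int8) for p1 in pi1
    ]) if pi1 else np.zeros((0, length), np.int8)
    return seq, marks


def sample_tkf_path(ancestor_length: int, lam: float, mu: float, t: float,
                    rng: np.random.Generator) -> AlignmentPath:
    """Sample an alignment skeleton from the TKF91 link fates.

    Per ancestral link: survive with probability e^{-mu t} (one aligned
    descendant plus Geometric(lam*beta) extra inserts); otherwise die,
    leaving no descendant with probability mu*beta / (1 - e^{-mu t}) and
    1 + Geometric(lam*beta) inserted descendants otherwise.  The immortal
    link contributes Geometric(lam*beta) leading inserts.
    """
    q = tkf_quantities(lam, mu, t)
    p_survive = math.exp(-mu * t)
    p_die_childless = (q.p0_prime / (1.0 - p_survive)
                       if p_survive < 1.0 else 0.0)

    def geometric_births() -> int:
        # number of failures before first success with success prob 1-lam*beta
        if q.lam_beta == 0.0:
            return 0
        return int(rng.geometric(1.0 - q.lam_beta)) - 1

    steps = ["Y"] * geometric_births()
    for _ in range(ancestor_length):
        if rng.random() < p_survive:
            steps.append("D")
            steps.extend("Y" * geometric_births())
        else:
            steps.append("X")
            if rng.random() >= p_die_childless:
                steps.extend("Y" * (1 + geometric_births()))
    return AlignmentPath("".join(steps))


def _draw_phi(pi1: float, rng: np.random.Generator) -> float:
    """Local equilibrium draw: Beta(1.5, 1.5(1-pi1)/pi1), mean pi1."""
    return float(rng.beta(1.5, 1.5 * (1.0 - pi1) / pi1))


def simulate_pair(config: SimulationConfig, rng: np.random.Generator,
                  identifier: str = "sim") -> SimulatedPair:
    """Simulate one homologous pair under the configured hypothesis."""
    theta = config.theta
    model = config.model
    pi_arr = config.pi_nuc.as_array()
    e_s = math.exp(-theta.s * config.t)
    e_k = [math.exp(-k * config.t) for k in theta.kappa]
    H = config.n_marks

    phi_truth = (tuple(_draw_phi(p1, rng) for p1 in config.pi1)
                 if model.uses_local_equilibria else None)
    anc_pi1 = phi_truth if phi_truth is not None else config.pi1

    while True:  # redraw in the rare case every descendant dies out
        seqA, marksA = sample_ancestor(config.ancestor_length, config.pi_nuc,
                                       anc_pi1, rng)
        path = sample_tkf_path(config.ancestor_length, config.lam, theta.mu,
                               config.t, rng)
        seqB: list[str] = []
        marksB: list[list[int]] = [[] for _ in range(H)]
        m = 0
        for step in path.steps:
            if step == "D":
                a = seqA[m]
                b = a if rng.random() < e_s else str(rng.choice(BASES, p=pi_arr))
                seqB.append(b)
                matched = b == a
                for h in range(H):
                    ah = int(marksA[h, m])
                    if matched or not model.depends_on_substitutions:
                        y = ah if rng.random() < e_k[h] else int(
                            rng.random() < config.pi1[h])
                    else:
                        y = int(rng.random() < config.pi1[h])
                    marksB[h].append(y)
                m += 1
            elif step == "X":
                m += 1
            else:  # insert
                seqB.append(str(rng.choice(BASES, p=pi_arr)))
                for h in range(H):
                    p1 = (phi_truth[h] if phi_truth is not None
                          else config.pi1[h])
                    marksB[h].append(int(rng.random() < p1))
        if seqB:
            break

    pair = HomologousPair(
        identifier=identifier,
        seqA=seqA,
        seqB="".join(seqB),
        tracksA=tuple(MarkTrack(h + 1, marksA[h]) for h in range(H)),
        tracksB=tuple(MarkTrack(h + 1, np.array(marksB[h], np.int8))
                      for h in range(H)),
    )
    return SimulatedPair(pair=pair, path=path, model=model, theta=theta,
                         phi_truth=phi_truth)


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[list[SimulatedPair], dict]:
    """Simulate n_pairs independent pairs plus a reproducibility manifest."""
    rng = np.random.default_rng(config.seed)
    sims = [simulate_pair(config, rng, identifier=f"sim{i:05d}")
            for i in range(config.n_pairs)]
    manifest = {
        "format_version": 1,
        "model": config.model.name,
        "theta": {"mu": config.theta.mu, "s": config.theta.s,
                  "kappa": list(config.theta.kappa)},
        "lambda": config.lam,
        "ancestor_length": config.ancestor_length,
        "n_pairs": config.n_pairs,
        "pi_nuc": list(config.pi_nuc.as_array()),
        "pi1": list(config.pi1),
        "t": config.t,
        "seed": config.seed,
        "pairs": [
            {"id": s.pair.identifier, "path": s.path.steps,
             "phi_truth": list(s.phi_truth) if s.phi_truth else None}
            for s in sims
        ],
    }
    return sims, manifest
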