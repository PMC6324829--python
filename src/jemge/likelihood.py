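"""Joint likelihood of a homologous pair under the four dependence models.

The observed unit is a *homologous pair*: two genomic regions, one per
species, each with one binary track per histone mark.  The joint probability
P(A, B) sums over all alignments (*paths*) of the two sequences, weighting
each path by its TKF91 probability and each aligned column by the
substitution and mark-switch kernels of the model in force:

* Model N — mark changes independent of sequence changes;
* Model M — mark changes depend on substitutions only;
* Model I — mark changes depend on indels only;
* Model B — mark changes depend on both.

The four models share one path space: monotone lattice paths from (0, 0) to
(sA, sB) with diagonal (match/mismatch), down (delete) and right (insert)
steps.  A diagonal step additionally carries a latent fate — the ancestral
link either survived (substitution kernel applies) or died and was replaced
by an unrelated insertion (equilibrium applies) — and the dynamic program
sums both fates per diagonal via the composite weight
``f·p1·G + (p1' - lam_beta·p0')·pi_b·(mark equilibrium factors)``.

``pair_log_likelihood`` evaluates the sum with an O(sA·sB) scaled dynamic
program (numba kernel); ``oracle_pair_log_likelihood`` evaluates the same
sum by explicit enumeration of paths and fates and is the ground truth the
DP is tested against on small pairs.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .evo_models import (
    BASE_INDEX,
    EvoParams,
    InvalidSymbolError,
    LocalEquilibria,
    ParameterDomainError,
    epi_switch_prob,
    nuc_substitution_prob,
    phi_marginal,
    tkf_quantities,
)

GAP = "-"

#: Hard cap for exhaustive path enumeration (Delannoy growth).
ORACLE_MAX_LEN = 6


class ModelKind(enum.IntEnum):
    """The four dependence hypotheses."""

    N = 0
    M = 1
    I = 2
    B = 3

    @property
    def uses_local_equilibria(self) -> bool:
        """Models N and M place local mark equilibria on indel columns."""
        return self in (ModelKind.N, ModelKind.M)

    @property
    def depends_on_substitutions(self) -> bool:
        return self in (ModelKind.M, ModelKind.B)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkTrack:
    """Binary states of one histone mark along one sequence."""

    index: int
    states: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.states, dtype=np.int8)
        if arr.ndim != 1:
            raise ValueError("mark track must be one-dimensional")
        if not np.all((arr == 0) | (arr == 1)):
            raise InvalidSymbolError("mark states must be 0/1")
        object.__setattr__(self, "states", arr)

    def __len__(self) -> int:
        return int(self.states.shape[0])


def encode_sequence(seq: str) -> np.ndarray:
    try:
        return np.array([BASE_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise InvalidSymbolError(f"non-base symbol in sequence: {exc}") from None


@dataclass(frozen=True)
class HomologousPair:
    """Two homologous regions with their mark tracks (0-based storage)."""

    identifier: str
    seqA: str
    seqB: str
    tracksA: tuple[MarkTrack, ...]
    tracksB: tuple[MarkTrack, ...]
    phi: LocalEquilibria | None = None

    def __post_init__(self) -> None:
        if len(self.seqA) < 1 or len(self.seqB) < 1:
            raise ValueError(f"{self.identifier}: sequences must be non-empty")
        if len(self.tracksA) != len(self.tracksB):
            raise ValueError(f"{self.identifier}: mark count differs between species")
        for tr, seq, side in ((self.tracksA, self.seqA, "A"),
                              (self.tracksB, self.seqB, "B")):
            for track in tr:
                if len(track) != len(seq):
                    raise ValueError(
                        f"{self.identifier}: track {track.index} length "
                        f"{len(track)} != sequence {side} length {len(seq)}")
        encode_sequence(self.seqA)
        encode_sequence(self.seqB)

    @property
    def sA(self) -> int:
        return len(self.seqA)

    @property
    def sB(self) -> int:
        return len(self.seqB)

    @property
    def n_marks(self) -> int:
        return len(self.tracksA)

    def marks_matrix(self, side: str) -> np.ndarray:
        """(H, length) int64 matrix of mark states for one side."""
        tracks = self.tracksA if side == "A" else self.tracksB
        length = self.sA if side == "A" else self.sB
        if not tracks:
            return np.zeros((0, length), dtype=np.int64)
        return np.stack([t.states.astype(np.int64) for t in tracks])


@dataclass(frozen=True)
class AlignmentColumn:
    """One aligned position: bases (or gaps) plus per-mark states.

    ``survived`` annotates diagonal columns with the latent TKF link fate;
    it is ignored for gap columns.
    """

    a0: str
    b0: str
    a_marks: tuple[int, ...] = ()
    b_marks: tuple[int, ...] = ()
    survived: bool = True

    def __post_init__(self) -> None:
        if self.a0 == GAP and self.b0 == GAP:
            raise ValueError("double-gap column is structurally impossible")
        for base in (self.a0, self.b0):
            if base != GAP and base not in BASE_INDEX:
                raise InvalidSymbolError(f"non-base symbol: {base!r}")

    @property
    def is_delete(self) -> bool:
        return self.b0 == GAP

    @property
    def is_insert(self) -> bool:
        return self.a0 == GAP

    @property
    def is_diagonal(self) -> bool:
        return self.a0 != GAP and self.b0 != GAP


@dataclass(frozen=True)
class AlignmentPath:
    """A monotone lattice path, stored as a step string over {D, X, Y}.

    D = diagonal (match/mismatch), X = delete (down), Y = insert (right).
    """

    steps: str

    def __post_init__(self) -> None:
        if set(self.steps) - set("DXY"):
            raise ValueError(f"invalid steps in {self.steps!r}")

    @property
    def sA(self) -> int:
        return sum(c in "DX" for c in self.steps)

    @property
    def sB(self) -> int:
        return sum(c in "DY" for c in self.steps)

    def counts(self) -> dict[str, int]:
        return {c: self.steps.count(c) for c in "DXY"}

    def columns(self, pair: HomologousPair,
                fates: tuple[bool, ...] | None = None) -> list[AlignmentColumn]:
        """Materialize the columns of this path for a concrete pair."""
        if self.sA != pair.sA or self.sB != pair.sB:
            raise ValueError("path does not project onto this pair")
        marksA = pair.marks_matrix("A")
        marksB = pair.marks_matrix("B")
        out: list[AlignmentColumn] = []
        m = n = 0
        fate_iter = iter(fates) if fates is not None else None
        for step in self.steps:
            if step == "D":
                survived = next(fate_iter) if fate_iter is not None else True
                out.append(AlignmentColumn(
                    pair.seqA[m], pair.seqB[n],
                    tuple(int(v) for v in marksA[:, m]),
                    tuple(int(v) for v in marksB[:, n]),
                    survived=survived))
                m += 1
                n += 1
            elif step == "X":
                out.append(AlignmentColumn(
                    pair.seqA[m], GAP,
                    tuple(int(v) for v in marksA[:, m]), ()))
                m += 1
            else:
                out.append(AlignmentColumn(
                    GAP, pair.seqB[n],
                    (), tuple(int(v) for v in marksB[:, n])))
                n += 1
        return out


def enumerate_alignments(sA: int, sB: int) -> list[AlignmentPath]:
    """All monotone lattice paths from (0,0) to (sA,sB); Delannoy many."""
    if sA < 0 or sB < 0:
        raise ValueError("lengths must be >= 0")
    if sA > ORACLE_MAX_LEN or sB > ORACLE_MAX_LEN:
        raise ValueError(
            f"refusing to enumerate alignments beyond length {ORACLE_MAX_LEN}")

    out: list[AlignmentPath] = []

    def recurse(m: int, n: int, prefix: list[str]) -> None:
        if m == sA and n == sB:
            out.append(AlignmentPath("".join(prefix)))
            return
        if m < sA and n < sB:
            recurse(m + 1, n + 1, prefix + ["D"])
        if m < sA:
            recurse(m + 1, n, prefix + ["X"])
        if n < sB:
            recurse(m, n + 1, prefix + ["Y"])

    recurse(0, 0, [])
    return out


# ---------------------------------------------------------------------------
# per-column conditional probabilities (the model case tables)
# ---------------------------------------------------------------------------

def column_cond_probs(model: ModelKind, col: AlignmentColumn, params: EvoParams,
                      phi: LocalEquilibria | None) -> tuple[float, float]:
    """P(a_h | a0, b0) and P(b_h | a_h, a0, b0), multiplied over marks.

    Implements the per-model case tables for the three column classes
    (diagonal, delete, insert); the latent fate of diagonal columns is not
    part of these tables (survival is assumed there).
    """
    if model.uses_local_equilibria and phi is None:
        raise ValueError(f"model {model.name} requires local equilibria phi")
    t = params.t
    pA = 1.0
    pB = 1.0
    for h, mp in enumerate(params.marks):
        if col.is_diagonal:
            a_h = col.a_marks[h]
            b_h = col.b_marks[h]
            pA *= mp.pi1 if a_h == 1 else mp.pi0
            if col.a0 == col.b0 or not model.depends_on_substitutions:
                pB *= epi_switch_prob(a_h, b_h, mp.kappa, t, mp.pi1)
            else:  # mismatch under M or B: descendant mark from equilibrium
                pB *= mp.pi1 if b_h == 1 else mp.pi0
        elif col.is_delete:
            a_h = col.a_marks[h]
            if model.uses_local_equilibria:
                pA *= phi_marginal(a_h, phi.phi_B1[h], mp.kappa, t, mp.pi1)
            else:
                pA *= mp.pi1 if a_h == 1 else mp.pi0
        else:  # insert
            b_h = col.b_marks[h]
            if model.uses_local_equilibria:
                pB *= phi_marginal(b_h, phi.phi_A1[h], mp.kappa, t, mp.pi1)
            else:
                pB *= mp.pi1 if b_h == 1 else mp.pi0
    return pA, pB


def path_log_prob(path_columns: list[AlignmentColumn], params: EvoParams) -> float:
    """Sequence-level log weight of one fate-annotated path.

    Product of per-column TKF factors: p0' per delete, lam_beta·pi_b per
    insert, f·p1 per surviving diagonal, (p1' - lam_beta·p0')·pi_b per died
    diagonal, times the immortal-link factor (1 - lam_beta).  The died
    composite factor can be negative; a non-positive total weight has no
    log and raises.
    """
    q = tkf_quantities(params.indel.lam, params.indel.mu, params.t)
    cdie = q.p1_prime - q.lam_beta * q.p0_prime
    w = q.one_minus_lam_beta
    for col in path_columns:
        if col.is_delete:
            w *= q.p0_prime
        elif col.is_insert:
            w *= q.lam_beta * params.nuc[col.b0]
        elif col.survived:
            w *= q.p1 * nuc_substitution_prob(col.a0, col.b0, params.s,
                                              params.t, params.nuc)
        else:
            w *= cdie * params.nuc[col.b0]
    if w <= 0.0:
        raise ValueError("path weight is non-positive; no log-probability")
    return math.log(w)


def _ancestor_seq_log_prob(pair: HomologousPair, params: EvoParams) -> float:
    """Sequence-only part of log P(A): TKF length equilibrium and base factors."""
    lam, mu = params.indel.lam, params.indel.mu
    ratio = lam / mu
    out = math.log1p(-ratio) + pair.sA * math.log(ratio)
    for base in pair.seqA:
        out += math.log(params.nuc[base])
    return out


def ancestor_log_prob(pair: HomologousPair, model: ModelKind,
                      params: EvoParams) -> float:
    """log P(A): TKF length equilibrium plus base (and, for I/B, mark) factors.

    For models N and M the ancestral mark equilibrium factors live inside the
    alignment recursion (pi^h_a on match columns, Phi_B on delete columns),
    so only the sequence part appears here.
    """
    out = _ancestor_seq_log_prob(pair, params)
    if not model.uses_local_equilibria:
        marksA = pair.marks_matrix("A")
        for h, mp in enumerate(params.marks):
            ones = int(marksA[h].sum())
            out += ones * math.log(mp.pi1) + (pair.sA - ones) * math.log(mp.pi0)
    return out


# ---------------------------------------------------------------------------
# dynamic program (scaled, numba)
# ---------------------------------------------------------------------------

@njit(cache=True, nogil=True)
def _dp_kernel(acode, bcode, amarks, bmarks, pib, est, g, pim, phiA, phiB,
               p1, p0p, lam_beta, cdie, model):  # pragma: no cover - jit
    sA = acode.shape[0]
    sB = bcode.shape[0]
    H = amarks.shape[0]
    local_phi = model <= 1  # N or M
    sub_dependent = model == 1 or model == 3  # M or B

    # per-position mark products on indel columns
    markA = np.ones(sA)
    markB = np.ones(sB)
    for h in range(H):
        for m in range(sA):
            if local_phi:
                markA[m] *= phiB[h, amarks[h, m]]
        for n in range(sB):
            if local_phi:
                markB[n] *= phiA[h, bmarks[h, n]]
            else:
                markB[n] *= pim[h, bmarks[h, n]]

    prev = np.zeros(sB + 1)
    cur = np.zeros(sB + 1)
    logscale = 0.0

    # row 0: immortal-link inserts
    prev[0] = 1.0
    for n in range(1, sB + 1):
        prev[n] = prev[n - 1] * lam_beta * pib[n - 1] * markB[n - 1]
    mx = prev.max()
    if mx > 0.0:
        for n in range(sB + 1):
            prev[n] /= mx
        logscale += np.log(mx)

    one_minus_est = 1.0 - est
    for m in range(1, sA + 1):
        am = acode[m - 1]
        wdel = p0p * markA[m - 1]
        cur[0] = wdel * prev[0]
        for n in range(1, sB + 1):
            bn = bcode[n - 1]
            # substitution kernel
            if am == bn:
                f = est + pib[n - 1] * one_minus_est
                matched = True
            else:
                f = pib[n - 1] * one_minus_est
                matched = False
            # mark factor on the surviving diagonal
            G = 1.0
            for h in range(H):
                ah = amarks[h, m - 1]
                bh = bmarks[h, n - 1]
                if sub_dependent and not matched:
                    gh = pim[h, bh]
                else:
                    gh = g[h, ah, bh]
                if local_phi:
                    gh *= pim[h, ah]
                G *= gh
            wdiag = (p1 * f * G
                     + cdie * pib[n - 1] * markB[n - 1] * markA[m - 1])
            cur[n] = (wdel * prev[n]
                      + lam_beta * pib[n - 1] * markB[n - 1] * cur[n - 1]
                      + wdiag * prev[n - 1])
        mx = cur.max()
        if mx > 0.0:
            for n in range(sB + 1):
                cur[n] /= mx
            logscale += np.log(mx)
        prev, cur = cur, prev

    if prev[sB] <= 0.0:
        return -np.inf
    return np.log(prev[sB]) + logscale


def _mark_kernels(pair: HomologousPair, params: EvoParams):
    """Precompute per-mark 2x2 switch kernels and equilibrium tables."""
    H = params.n_marks
    g = np.empty((H, 2, 2))
    pim = np.empty((H, 2))
    phiA = np.ones((H, 2))
    phiB = np.ones((H, 2))
    for h, mp in enumerate(params.marks):
        for x in (0, 1):
            for y in (0, 1):
                g[h, x, y] = epi_switch_prob(x, y, mp.kappa, params.t, mp.pi1)
        pim[h, 0] = mp.pi0
        pim[h, 1] = mp.pi1
        if pair.phi is not None:
            for y in (0, 1):
                phiA[h, y] = ((1.0 - pair.phi.phi_A1[h]) * g[h, 0, y]
                              + pair.phi.phi_A1[h] * g[h, 1, y])
                phiB[h, y] = ((1.0 - pair.phi.phi_B1[h]) * g[h, 0, y]
                              + pair.phi.phi_B1[h] * g[h, 1, y])
    return g, pim, phiA, phiB


def pair_log_likelihood(pair: HomologousPair, model: ModelKind,
                        params: EvoParams) -> float:
    """log P(A, B) under one model: ancestor part plus the alignment sum."""
    if params.n_marks != pair.n_marks:
        raise ValueError("parameter mark count differs from the pair's")
    if model.uses_local_equilibria and pair.phi is None:
        raise ValueError(f"model {model.name} requires local equilibria on the pair")
    q = tkf_quantities(params.indel.lam, params.indel.mu, params.t)
    g, pim, phiA, phiB = _mark_kernels(pair, params)
    acode = encode_sequence(pair.seqA)
    bcode = encode_sequence(pair.seqB)
    pib = params.nuc.as_array()[bcode]
    est = math.exp(-params.s * params.t)
    cdie = q.p1_prime - q.lam_beta * q.p0_prime
    dp = _dp_kernel(acode, bcode, pair.marks_matrix("A"), pair.marks_matrix("B"),
                    pib, est, g, pim, phiA, phiB,
                    q.p1, q.p0_prime, q.lam_beta, cdie, int(model))
    return (ancestor_log_prob(pair, model, params)
            + math.log(q.one_minus_lam_beta) + dp)


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

def oracle_pair_log_likelihood(pair: HomologousPair, model: ModelKind,
                               params: EvoParams) -> float:
    """Explicit path-and-fate summation of the same likelihood.

    Enumerates every lattice path and, within each path, both latent fates of
    every diagonal column, multiplying per-column TKF and mark factors.  The
    per-column conditional products already contain the ancestral mark
    marginal, so only the sequence part of P(A) is added.  Summation is
    carried out in linear space because died-diagonal composite weights may
    be negative (emission-equivalent path classes still aggregate to
    non-negative mass).  Guarded to tiny pairs.
    """
    if pair.sA > ORACLE_MAX_LEN or pair.sB > ORACLE_MAX_LEN:
        raise ValueError("oracle is restricted to tiny pairs")
    if model.uses_local_equilibria and pair.phi is None:
        raise ValueError(f"model {model.name} requires local equilibria on the pair")
    q = tkf_quantities(params.indel.lam, params.indel.mu, params.t)
    cdie = q.p1_prime - q.lam_beta * q.p0_prime
    total = 0.0
    for path in enumerate_alignments(pair.sA, pair.sB):
        n_diag = path.steps.count("D")
        for fates in itertools.product((True, False), repeat=n_diag):
            w = q.one_minus_lam_beta
            for col in path.columns(pair, fates):
                if col.is_delete:
                    pA, _ = column_cond_probs(model, col, params, pair.phi)
                    w *= q.p0_prime * pA
                elif col.is_insert:
                    _, pB = column_cond_probs(model, col, params, pair.phi)
                    w *= q.lam_beta * params.nuc[col.b0] * pB
                elif col.survived:
                    pA, pB = column_cond_probs(model, col, params, pair.phi)
                    w *= (q.p1
                          * nuc_substitution_prob(col.a0, col.b0, params.s,
                                                  params.t, params.nuc)
                          * pA * pB)
                else:
                    # died diagonal: unrelated delete + insert in one column
                    del_col = AlignmentColumn(col.a0, GAP, col.a_marks, ())
                    ins_col = AlignmentColumn(GAP, col.b0, (), col.b_marks)
                    pA, _ = column_cond_probs(model, del_col, params, pair.phi)
                    _, pB = column_cond_probs(model, ins_col, params, pair.phi)
                    w *= cdie * params.nuc[col.b0] * pA * pB
            total += w
    if total <= 0.0:
        return -math.inf
    return _ancestor_seq_log_prob(pair, params) + math.log(total)
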