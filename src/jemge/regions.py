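"""Per-region model comparison and dependence metrics.

Every homologous pair is scored under all four models; the best model (by
likelihood) classifies the region.  Classification frequencies give the
mixing coefficients

    a = P(ind = 0) = freq(N) + freq(M)      (mark changes indel-independent)
    b = P(mut = 0) = freq(N) + freq(I)      (mark changes substitution-independent)

from which the substitution- and indel-conditional likelihoods are built as
two-component mixtures, e.g. P(A,B | mut=0) = a P_N + (1-a) P_I.  The
normalized contrasts

    r_ind = [l(ind=1) - l(ind=0)] / |l(ind=1) + l(ind=0)|   (or / (sA+sB))
    r_mut = [l(mut=1) - l(mut=0)] / |l(mut=1) + l(mut=0)|

are positive when the dependent side fits better.  Ties in classification
break toward the simpler/independent hypothesis in the order N > M > I > B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .inference import ALL_MODELS, Dataset, DatasetLikelihood, MixtureFit, ThetaFree
from .likelihood import ModelKind

#: Deterministic tie-break preference, most-preferred first.
TIE_ORDER = (ModelKind.N, ModelKind.M, ModelKind.I, ModelKind.B)


class UndefinedMetricError(ValueError):
    """The normalization denominator vanished; the metric is undefined."""


@dataclass(frozen=True)
class RegionLikelihoods:
    """The four per-model log-likelihoods of one homologous pair."""

    identifier: str
    logL: dict[ModelKind, float]
    sA: int
    sB: int

    def __post_init__(self) -> None:
        if set(self.logL) != set(ALL_MODELS):
            raise ValueError("need exactly the four model log-likelihoods")
        if not all(math.isfinite(v) for v in self.logL.values()):
            raise ValueError(f"{self.identifier}: non-finite log-likelihood")


@dataclass(frozen=True)
class DependenceCoefficients:
    """a = P(ind=0), b = P(mut=0)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.b <= 1.0):
            raise ValueError("coefficients must lie in [0, 1]")


@dataclass(frozen=True)
class RegionReport:
    likelihoods: RegionLikelihoods
    best_model: ModelKind
    r_ind: float | None
    r_mut: float | None
    r_ind_len: float
    r_mut_len: float

    @property
    def identifier(self) -> str:
        return self.likelihoods.identifier


def classify_pair(likelihoods: RegionLikelihoods) -> ModelKind:
    """Argmax model; exact ties resolve in the order N > M > I > B."""
    best = TIE_ORDER[0]
    for model in TIE_ORDER[1:]:
        if likelihoods.logL[model] > likelihoods.logL[best]:
            best = model
    return best


def dependence_coefficients(
        classifications: list[ModelKind]) -> DependenceCoefficients:
    """Hard-classification frequencies of indel/substitution independence."""
    if not classifications:
        raise ValueError("empty classification list")
    n = len(classifications)
    counts = {m: classifications.count(m) for m in ALL_MODELS}
    return DependenceCoefficients(
        a=(counts[ModelKind.N] + counts[ModelKind.M]) / n,
        b=(counts[ModelKind.N] + counts[ModelKind.I]) / n,
    )


def coefficients_from_mixture(fit: MixtureFit) -> DependenceCoefficients:
    """Soft alternative: coefficients from EM priors alpha."""
    return DependenceCoefficients(
        a=fit.alpha[ModelKind.N] + fit.alpha[ModelKind.M],
        b=fit.alpha[ModelKind.N] + fit.alpha[ModelKind.I],
    )


def conditional_log_likelihoods(
        rl: RegionLikelihoods, coef: DependenceCoefficients,
) -> tuple[float, float, float, float]:
    """(l_mut0, l_mut1, l_ind0, l_ind1) as log two-component mixtures.

    l_mut0 = log[a P_N + (1-a) P_I]      l_mut1 = log[a P_M + (1-a) P_B]
    l_ind0 = log[b P_N + (1-b) P_M]      l_ind1 = log[b P_I + (1-b) P_B]
    """
    def mix(w: float, l1: float, l2: float) -> float:
        if w == 1.0:
            return l1
        if w == 0.0:
            return l2
        return float(logsumexp([l1, l2], b=[w, 1.0 - w]))

    lN, lM = rl.logL[ModelKind.N], rl.logL[ModelKind.M]
    lI, lB = rl.logL[ModelKind.I], rl.logL[ModelKind.B]
    return (mix(coef.a, lN, lI), mix(coef.a, lM, lB),
            mix(coef.b, lN, lM), mix(coef.b, lI, lB))


def r_metrics(l0: float, l1: float, normalization: str = "sum_abs",
              sA: int = 0, sB: int = 0) -> float:
    """Normalized log-likelihood contrast r = [l1 - l0] / denominator.

    ``sum_abs`` divides by |l1 + l0|; ``length`` divides by sA + sB.
    Positive values favor the dependent (l1) side.
    """
    if not (math.isfinite(l0) and math.isfinite(l1)):
        raise ValueError("log-likelihoods must be finite")
    num = l1 - l0
    if normalization == "sum_abs":
        denom = abs(l1 + l0)
        if denom == 0.0:
            raise UndefinedMetricError("l1 = -l0: sum normalization undefined")
    elif normalization == "length":
        denom = sA + sB
        if denom <= 0:
            raise ValueError("length normalization needs sA + sB > 0")
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return num / denom


def region_report(rl: RegionLikelihoods,
                  coef: DependenceCoefficients) -> RegionReport:
    """Classification plus both normalizations of r_ind and r_mut."""
    l_mut0, l_mut1, l_ind0, l_ind1 = conditional_log_likelihoods(rl, coef)
    try:
        r_ind = r_metrics(l_ind0, l_ind1, "sum_abs")
    except UndefinedMetricError:
        r_ind = None
    try:
        r_mut = r_metrics(l_mut0, l_mut1, "sum_abs")
    except UndefinedMetricError:
        r_mut = None
    return RegionReport(
        likelihoods=rl,
        best_model=classify_pair(rl),
        r_ind=r_ind,
        r_mut=r_mut,
        r_ind_len=r_metrics(l_ind0, l_ind1, "length", rl.sA, rl.sB),
        r_mut_len=r_metrics(l_mut0, l_mut1, "length", rl.sA, rl.sB),
    )


def score_dataset(dataset: Dataset,
                  theta_by_model: dict[ModelKind, ThetaFree],
                  threads: int = 1) -> list[RegionLikelihoods]:
    """Four per-model log-likelihoods for every pair, at the fitted thetas."""
    eng = DatasetLikelihood(dataset, threads=threads)
    cols = {m: eng.pair_logliks(theta_by_model[m], (m,))[:, 0]
            for m in ALL_MODELS}
    out = []
    for i, pair in enumerate(dataset.pairs):
        out.append(RegionLikelihoods(
            identifier=pair.identifier,
            logL={m: float(cols[m][i]) for m in ALL_MODELS},
            sA=pair.sA, sB=pair.sB))
    return out


def analyze_regions(dataset: Dataset,
                    theta_by_model: dict[ModelKind, ThetaFree],
                    coef: DependenceCoefficients | None = None,
                    threads: int = 1) -> list[RegionReport]:
    """Full per-region workflow: score, classify, coefficients, r metrics."""
    rls = score_dataset(dataset, theta_by_model, threads=threads)
    if coef is None:
        coef = dependence_coefficients([classify_pair(rl) for rl in rls])
    return [region_report(rl, coef) for rl in rls]


def quadrant_summary(reports: list[RegionReport]) -> dict[str, int]:
    """Counts per (sign r_ind, sign r_mut) quadrant; zeros count as negative.

    Keys: ``q1`` (+,+), ``q2`` (-,+), ``q3`` (-,-), ``q4`` (+,-); reports with
    an undefined metric are skipped and reported under ``undefined``.
    """
    out = {"q1": 0, "q2": 0, "q3": 0, "q4": 0, "undefined": 0}
    for rep in reports:
        if rep.r_ind is None or rep.r_mut is None:
            out["undefined"] += 1
            continue
        ind_pos = rep.r_ind > 0
        mut_pos = rep.r_mut > 0
        if ind_pos and mut_pos:
            out["q1"] += 1
        elif mut_pos:
            out["q2"] += 1
        elif ind_pos:
            out["q4"] += 1
        else:
            out["q3"] += 1
    return out


def select_top_fraction(reports: list[RegionReport], key: str,
                        fraction: float, tail: str = "upper"
                        ) -> list[RegionReport]:
    """The ceil(fraction*n) reports most extreme in ``key``.

    ``key`` is a RegionReport attribute (e.g. ``r_ind``); None values are
    excluded.  Ordering is deterministic: by value, then by region id.
    """
    if not reports:
        raise ValueError("empty report list")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    defined = [r for r in reports if getattr(r, key) is not None]
    k = math.ceil(fraction * len(defined))
    reverse = tail == "upper"
    ordered = sorted(defined,
                     key=lambda r: (getattr(r, key), r.identifier),
                     reverse=reverse)
    return ordered[:k]
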