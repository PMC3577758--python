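"""Summary statistics, information transfer rate, and behavior correlations."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class SummaryStat:
    mean: float
    sd: float
    n: int
    label: str = ""


@dataclass
class ItrResult:
    bits_per_selection: float
    selections_per_minute: float
    bits_per_minute: float
    n_classes: int
    accuracy: float
    selection_time_s: float


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of printed summary tables."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def summarize(values, label: str = "") -> SummaryStat:
    """Arithmetic mean and sample SD (n-1 denominator; sd = 0 for n = 1)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty collection")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SummaryStat(mean=float(arr.mean()), sd=sd, n=int(arr.size), label=label)


def itr_wolpaw(P: float, N: int = 2, T: float = 1.1) -> ItrResult:
    """Information transfer rate from accuracy P, class count N, time T (s).

    Bits per selection B = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)),
    with 0*log2(0) taken as 0, scaled by 60/T selections per minute.
    Below-chance accuracies (P < 1/N) are floored at 0 bits: the formula
    turns non-monotone there and a below-chance classifier transmits no
    usable information under this convention.
    """
    if N < 2:
        raise ValueError("need at least 2 classes")
    if T <= 0:
        raise ValueError("selection time must be positive")
    if not 0.0 <= P <= 1.0:
        raise ValueError("accuracy P must lie in [0, 1]")
    if P < 1.0 / N:
        bits = 0.0
    else:
        bits = math.log2(N)
        if P > 0:
            bits += P * math.log2(P)
        if P < 1:
            bits += (1.0 - P) * math.log2((1.0 - P) / (N - 1))
    per_min = 60.0 / T
    return ItrResult(
        bits_per_selection=bits,
        selections_per_minute=per_min,
        bits_per_minute=bits * per_min,
        n_classes=N,
        accuracy=P,
        selection_time_s=T,
    )


def behavior_correlation(accuracies, behavior) -> tuple[float, float]:
    """Pearson r (with two-sided p via the t transform) between paired vectors.

    Used to relate per-direction classification accuracy to behavioral
    measures such as localization accuracy or counting error.
    """
    a = np.asarray(list(accuracies), dtype=float)
    b = np.asarray(list(behavior), dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
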