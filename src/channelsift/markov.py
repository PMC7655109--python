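"""Interaction probabilities with Bayesian two-state Markov uncertainty.

Per-frame bits are averaged over frames and subunits to give occupancy
probabilities; the uncertainty of each probability comes from a two-state
Markov model whose transition-matrix posterior is sampled under symmetric
Dirichlet (add-count Beta) priors.  The stationary probability of a sampled
chain is p01 / (p01 + p10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from channelsift.fingerprints import BIT_NAMES, FingerprintMatrix

STABILITY_LABELS = ("rare", "occasional", "stable", "very_stable")


@dataclass
class MarkovEstimate:
    """Posterior summary of a two-state chain's stationary probability."""

    n00: int
    n01: int
    n10: int
    n11: int
    prior_count: float
    posterior_samples: np.ndarray  # (n_samples, 2) of (p01, p10)
    stationary_mean: float
    ci_low: float
    ci_high: float
    seed: int

    @property
    def ci_half_width(self) -> float:
        return 0.5 * (self.ci_high - self.ci_low)


def occupancy_probability(matrix: FingerprintMatrix,
                          residue: tuple[str, int],
                          bit: Union[int, str]) -> float:
    """Mean of a bit over all frames and all subunits for one residue."""
    if isinstance(bit, str):
        if bit not in BIT_NAMES:
            raise KeyError(f"unknown bit {bit!r}")
        bit = BIT_NAMES.index(bit)
    residue = tuple(residue)
    try:
        r = matrix.residues.index(residue)
    except ValueError as exc:
        raise KeyError(f"unknown residue {residue!r}") from exc
    return float(matrix.bits[r, :, :, bit].mean())


def transition_counts(series_list: Sequence[Sequence[int]]) -> tuple[int, int, int, int]:
    """Pooled (n00, n01, n10, n11); no transition crosses a series boundary."""
    n00 = n01 = n10 = n11 = 0
    for series in series_list:
        arr = np.asarray(series)
        if arr.ndim != 1 or len(arr) < 2:
            raise ValueError("each series must be 1-D with length >= 2")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("series must be binary 0/1")
        a, b = arr[:-1], arr[1:]
        n00 += int(np.sum((a == 0) & (b == 0)))
        n01 += int(np.sum((a == 0) & (b == 1)))
        n10 += int(np.sum((a == 1) & (b == 0)))
        n11 += int(np.sum((a == 1) & (b == 1)))
    return n00, n01, n10, n11


def markov_error(series_list: Sequence[Sequence[int]],
                 prior_count: float = 1.0,
                 n_samples: int = 10_000,
                 ci_level: float = 0.95,
                 seed: int = 0) -> MarkovEstimate:
    """Posterior of the stationary probability of a pooled two-state chain.

    Row-wise conjugate posteriors: p01 ~ Beta(n01 + prior, n00 + prior) and
    p10 ~ Beta(n10 + prior, n11 + prior).  The stationary probability of each
    draw is p01 / (p01 + p10); the (impossible under positive priors) case
    p01 + p10 = 0 is guarded by rejection.  The credible interval is
    equal-tailed at ``ci_level``.
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not (0 < ci_level < 1):
        raise ValueError("ci_level must be in (0, 1)")
    n00, n01, n10, n11 = transition_counts(series_list)
    rng = np.random.default_rng(seed)
    p01 = rng.beta(n01 + prior_count, n00 + prior_count, size=n_samples)
    p10 = rng.beta(n10 + prior_count, n11 + prior_count, size=n_samples)
    bad = (p01 + p10) == 0
    while bad.any():
        k = int(bad.sum())
        p01[bad] = rng.beta(n01 + prior_count, n00 + prior_count, size=k)
        p10[bad] = rng.beta(n10 + prior_count, n11 + prior_count, size=k)
        bad = (p01 + p10) == 0
    stationary = p01 / (p01 + p10)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(stationary, [alpha, 1.0 - alpha])
    return MarkovEstimate(
        n00=n00, n01=n01, n10=n10, n11=n11, prior_count=prior_count,
        posterior_samples=np.column_stack([p01, p10]),
        stationary_mean=float(stationary.mean()),
        ci_low=float(lo), ci_high=float(hi), seed=seed,
    )


def stability_class(probability: float) -> str:
    """Bin a probability into half-open, lower-exclusive stability classes.

    >0.75 very_stable; >0.50 stable; >0.25 occasional; <=0.25 rare.
    """
    if not (0.0 <= probability <= 1.0):
        raise ValueError(f"probability {probability} outside [0, 1]")
    if probability > 0.75:
        return "very_stable"
    if probability > 0.50:
        return "stable"
    if probability > 0.25:
        return "occasional"
    return "rare"


def summarize_fingerprints(matrix: FingerprintMatrix,
                           prior_count: float = 1.0,
                           n_samples: int = 10_000,
                           ci_level: float = 0.95,
                           seed: int = 0,
                           min_probability: float = 0.0) -> pd.DataFrame:
    """Per-(residue, bit) probability, credible half-width, stability class.

    Each subunit's per-frame bit series enters the Markov error model as an
    independent replicate (transition counts pooled, no cross-series
    transitions).
    """
    rows = []
    for r, res in enumerate(matrix.residues):
        for b, bit_name in enumerate(BIT_NAMES):
            prob = float(matrix.bits[r, :, :, b].mean())
            if prob < min_probability:
                continue
            series = [matrix.bits[r, s, :, b].astype(int) for s in range(len(matrix.subunits))]
            series = [s for s in series if len(s) >= 2]
            if series:
                est = markov_error(series, prior_count=prior_count,
                                   n_samples=n_samples, ci_level=ci_level,
                                   seed=seed + 1000 * r + b)
                err = est.ci_half_width
            else:
                err = float("nan")
            rows.append({
                "residue": matrix.residue_label(res),
                "bit": bit_name,
                "probability": prob,
                "error": err,
                "stability_class": stability_class(prob),
            })
    return pd.DataFrame(rows)
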