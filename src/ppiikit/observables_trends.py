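"""Scalar-observable statistics and PPII-content trends.

Covers block-averaged error estimates for correlated per-frame series
(Flyvbjerg-Petersen doubling), the ordinary-least-squares regression of
PPII content on proline count, and a simple localization score
contrasting the PPII fraction at proline positions with the rest of the
chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rama_ss import SSProfile

__all__ = [
    "RegressionResult",
    "block_error",
    "ppii_vs_proline",
    "ppii_localization",
]

logger = logging.getLogger(__name__)


def block_error(series, max_blocks: int = 16) -> tuple[float, float]:
    """Mean and block-averaged standard error of a per-frame series.

    Block sizes double from 1 until at most ``max_blocks`` blocks remain;
    at each size the standard error of the block means is computed.  The
    reported error is the first estimate that changes by less than 5%
    over a doubling (the plateau); if no plateau appears the largest-block
    estimate is returned with a logged warning.  The mean never depends
    on the blocking schedule.
    """
    values = np.asarray(series, dtype=float).ravel()
    if values.size < 16:
        raise ValueError("need at least 16 frames for a block-error estimate")
    if max_blocks < 2:
        raise ValueError("max_blocks must be at least 2")
    mean = float(values.mean())

    estimates = []
    block = 1
    while values.size // block >= 2:
        n_blocks = values.size // block
        trimmed = values[: n_blocks * block].reshape(n_blocks, block)
        block_means = trimmed.mean(axis=1)
        estimates.append(float(block_means.std(ddof=1) / np.sqrt(n_blocks)))
        if n_blocks <= max_blocks:
            break
        block *= 2

    if estimates[0] == 0.0:
        return mean, 0.0
    for previous, current in zip(estimates, estimates[1:]):
        if previous > 0 and abs(current - previous) / previous < 0.05:
            return mean, current
    logger.warning(
        "block-error estimate did not plateau; returning the largest-block value"
    )
    return mean, estimates[-1]


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary: slope m, intercept c, r^2, two-sided slope p, n."""

    m: float
    c: float
    r2: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("r2 must lie in [0, 1]")
        if self.n < 3:
            raise ValueError("need at least 3 points for a defined p-value")

    def to_dict(self) -> dict:
        return {
            "kind": "RegressionResult",
            "m": self.m, "c": self.c, "r2": self.r2, "p": self.p, "n": self.n,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RegressionResult":
        return cls(
            m=float(data["m"]), c=float(data["c"]), r2=float(data["r2"]),
            p=float(data["p"]), n=int(data["n"]),
        )


def ppii_vs_proline(points) -> RegressionResult:
    """Regress PPII content (percent) on the number of proline residues.

    ``points`` is an iterable of (pro_count, ppii_percent) pairs.  The
    p-value is the standard two-sided t-test on the slope.
    """
    pairs = [(float(x), float(y)) for x, y in points]
    if len(pairs) < 3:
        raise ValueError("need at least 3 points")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.all(x == x[0]):
        raise ValueError("all proline counts identical; slope undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        m=float(fit.slope), c=float(fit.intercept),
        r2=float(fit.rvalue**2), p=float(fit.pvalue), n=len(pairs),
    )


def ppii_localization(
    profile: SSProfile, pro_positions
) -> tuple[float, float, float]:
    """How much PPII concentrates on the prolines.

    Returns ``(score, mean_at_pro, mean_elsewhere)`` where the score is
    the mean per-residue PPII fraction at the given 1-based proline
    positions minus the mean over all other residues; residues with
    undefined profiles (chain termini) are excluded from both means.
    """
    positions = set(int(p) for p in pro_positions)
    if not positions:
        raise ValueError("empty proline position set")
    table = profile.per_residue
    n_res = len(table)
    if any(p < 1 or p > n_res for p in positions):
        raise ValueError("proline position outside the chain")
    ppii = table["PPII"].to_numpy()
    residues = table["residue"].to_numpy()
    defined = np.isfinite(ppii)
    at_pro = defined & np.isin(residues, list(positions))
    elsewhere = defined & ~np.isin(residues, list(positions))
    if not at_pro.any() or not elsewhere.any():
        raise ValueError("need defined PPII fractions both at and off the prolines")
    mean_pro = float(ppii[at_pro].mean())
    mean_other = float(ppii[elsewhere].mean())
    return mean_pro - mean_other, mean_pro, mean_other
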