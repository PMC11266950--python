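"""Wald ratios, inverse-variance-weighted meta-analysis and diagnostics.

The instrumental-variable machinery of two-sample Mendelian randomization:
per-variant Wald ratio estimates (outcome effect over exposure effect, with a
delta-method standard error), fixed- and random-effects inverse-variance
weighted (IVW) pooling, Cochran's Q heterogeneity statistic, leave-one-out
sensitivity analysis, and the instrument-strength F-statistic.

Random-effects flavour
----------------------
The default random-effects model is *multiplicative*: the fixed-effect
standard error ``1/sqrt(sum w_i)`` is inflated by
``phi = max(1, sqrt(Q / (k - 1)))``, so that under-dispersion never shrinks
the SE below the fixed-effect one.  An additive DerSimonian–Laird mode is
provided as an alternative.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedPair

__all__ = [
    "WaldEstimate",
    "IVWResult",
    "FStat",
    "wald_ratio",
    "ivw",
    "leave_one_out",
    "f_statistic",
    "report_or",
    "write_mr_table",
    "read_mr_table",
]

_MODES = ("fixed", "multiplicative_random", "additive_random")


def report_or(
    theta: float, se: float, level: float = 0.95
) -> tuple[float, float, float, float]:
    """Express a log-odds estimate as OR, CI bounds and two-sided normal p."""
    if not (se > 0):
        raise ValueError(f"se must be > 0, got {se}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    # Extreme Wald ratios (near-degenerate instruments) overflow exp; report
    # inf rather than raising so weak-instrument simulations stay runnable.
    with np.errstate(over="ignore"):
        or_ = float(np.exp(theta))
        lo = float(np.exp(theta - z * se))
        hi = float(np.exp(theta + z * se))
    return or_, lo, hi, 2.0 * stats.norm.sf(abs(theta / se))


@dataclass(frozen=True)
class WaldEstimate:
    """Per-SNP causal estimate theta = beta_outcome / beta_exposure."""

    rsid: str
    theta: float
    se: float
    or_: float
    ci: tuple[float, float]
    pval: float

    @classmethod
    def from_theta(
        cls, rsid: str, theta: float, se: float, level: float = 0.95
    ) -> "WaldEstimate":
        or_, lo, hi, p = report_or(theta, se, level)
        return cls(rsid, theta, se, or_, (lo, hi), p)


def wald_ratio(
    pair: HarmonizedPair | tuple[float, float, float],
    second_order: bool = False,
    level: float = 0.95,
    se_bx: float | None = None,
) -> WaldEstimate:
    """Per-variant causal estimate by the Wald ratio method.

    Accepts a harmonized exposure/outcome pair, or a bare
    ``(beta_exposure, beta_outcome, se_outcome)`` triple.

    The default standard error is first-order delta method,
    ``se_outcome / |beta_exposure|`` (exposure-side uncertainty ignored).
    With ``second_order=True`` the exposure term
    ``theta^2 * se_bx^2 / bx^2`` is added in quadrature.
    """
    if isinstance(pair, HarmonizedPair):
        if not pair.kept or pair.outcome is None:
            raise ValueError(f"{pair.rsid}: cannot estimate from a dropped pair")
        rsid = pair.rsid
        bx, by, se_by = pair.exposure.beta, pair.outcome.beta, pair.outcome.se
        if se_bx is None:
            se_bx = pair.exposure.se
    else:
        bx, by, se_by = pair
        rsid = "."
    if bx == 0:
        raise ZeroDivisionError(f"{rsid}: degenerate instrument (beta_exposure = 0)")
    theta = by / bx
    var = (se_by / bx) ** 2
    if second_order:
        if se_bx is None:
            raise ValueError("second-order delta method needs the exposure SE")
        var += theta**2 * se_bx**2 / bx**2
    return WaldEstimate.from_theta(rsid, theta, math.sqrt(var), level)


@dataclass(frozen=True)
class IVWResult:
    """Pooled causal estimate with heterogeneity context.

    ``Q`` is Cochran's statistic on ``q_df = k - 1`` degrees of freedom
    (absent when k = 1).  ``se_fixed`` is the fixed-effect SE; ``se_used`` is
    what the CI and p-value are built from (inflated by ``phi`` in
    multiplicative random-effects mode).
    """

    theta_hat: float
    se_fixed: float
    se_used: float
    phi: float
    or_: float
    ci: tuple[float, float]
    pval: float
    Q: float | None
    q_df: int | None
    q_pval: float | None
    k: int
    mode: str
    tau2: float | None = None


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")


def ivw(
    estimates: Sequence[WaldEstimate],
    mode: str = "multiplicative_random",
    level: float = 0.95,
) -> IVWResult:
    """Inverse-variance-weighted meta-analysis of per-variant estimates.

    Weights are ``w_i = 1 / se_i^2``; the pooled estimate is the weighted
    mean.  ``Q = sum w_i (theta_i - theta_hat)^2``.  A single estimate is
    returned as the pooled result with Q absent rather than raising, which
    keeps downstream leave-one-out handling uniform.
    """
    _check_mode(mode)
    if len(estimates) == 0:
        raise ValueError("ivw needs at least one estimate")
    theta = np.array([e.theta for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    k = len(estimates)
    w = 1.0 / se**2
    theta_hat = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(1.0 / math.sqrt(np.sum(w)))

    if k == 1:
        or_, lo, hi, p = report_or(theta_hat, se_fixed, level)
        return IVWResult(
            theta_hat, se_fixed, se_fixed, 1.0, or_, (lo, hi), p,
            None, None, None, 1, mode,
        )

    Q = float(np.sum(w * (theta - theta_hat) ** 2))
    q_df = k - 1
    q_pval = float(stats.chi2.sf(Q, q_df))

    tau2 = None
    if mode == "fixed":
        phi, se_used = 1.0, se_fixed
    elif mode == "multiplicative_random":
        phi = max(1.0, math.sqrt(Q / q_df))
        se_used = se_fixed * phi
    else:  # additive_random: DerSimonian-Laird between-variant variance
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (Q - q_df) / c)
        w_star = 1.0 / (se**2 + tau2)
        theta_hat = float(np.sum(w_star * theta) / np.sum(w_star))
        se_used = float(1.0 / math.sqrt(np.sum(w_star)))
        phi = se_used / se_fixed

    or_, lo, hi, p = report_or(theta_hat, se_used, level)
    return IVWResult(
        theta_hat, se_fixed, se_used, phi, or_, (lo, hi), p,
        Q, q_df, q_pval, k, mode, tau2,
    )


def leave_one_out(
    estimates: Sequence[WaldEstimate],
    mode: str = "multiplicative_random",
    level: float = 0.95,
) -> list[tuple[str, IVWResult]]:
    """Re-pool after excluding each variant in turn.

    Q and the random-effects inflation are recomputed on each reduced set.
    """
    if len(estimates) < 2:
        raise ValueError("leave-one-out needs at least two estimates")
    results = []
    for i, excluded in enumerate(estimates):
        rest = [e for j, e in enumerate(estimates) if j != i]
        results.append((excluded.rsid, ivw(rest, mode=mode, level=level)))
    return results


@dataclass(frozen=True)
class FStat:
    """Instrument-strength F-statistic and the quantities that produced it."""

    value: float
    r2: float
    n: int
    k: int


def f_statistic(r2: float, n: int, k: int) -> FStat:
    """Approximate F-statistic for instrument strength.

    ``F = (r2 / (1 - r2)) * ((n - k - 1) / k)`` where ``r2`` is the
    proportion of exposure variance explained by the ``k`` instruments and
    ``n`` is the GWAS sample size supplied by the caller.  F well above 10 is
    the conventional strong-instrument threshold.

    .. note::
       Which ``n`` to use is a modelling choice.  The textbook choice is the
       exposure-GWAS sample size; some published analyses instead plug in the
       outcome-GWAS sample size.  This function computes from whatever ``n``
       it is given and records it in the result.
    """
    if not (0.0 < r2 < 1.0):
        raise ValueError(f"r2 must lie in (0, 1), got {r2}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise ValueError(f"n must exceed k + 1, got n={n}, k={k}")
    value = (r2 / (1.0 - r2)) * ((n - k - 1) / k)
    return FStat(value, r2, n, k)


# ---------------------------------------------------------------------------
# Tabular result I/O (one IVW row plus one row per Wald estimate, per outcome)

_TABLE_COLUMNS = [
    "outcome", "method", "rsid", "f_stat", "or", "ci_lower", "ci_upper", "pval",
    "q", "q_pval",
]


def write_mr_table(
    path: str | Path,
    outcome: str,
    pooled: IVWResult,
    estimates: Sequence[WaldEstimate],
    fstat: FStat | None = None,
    append: bool = False,
) -> None:
    """Write results as TSV: an IVW summary row, then one row per variant."""
    rows = [
        {
            "outcome": outcome,
            "method": "ivw",
            "rsid": ".",
            "f_stat": fstat.value if fstat else np.nan,
            "or": pooled.or_,
            "ci_lower": pooled.ci[0],
            "ci_upper": pooled.ci[1],
            "pval": pooled.pval,
            "q": np.nan if pooled.Q is None else pooled.Q,
            "q_pval": np.nan if pooled.q_pval is None else pooled.q_pval,
        }
    ]
    for e in estimates:
        rows.append(
            {
                "outcome": outcome,
                "method": "wald_ratio",
                "rsid": e.rsid,
                "f_stat": np.nan,
                "or": e.or_,
                "ci_lower": e.ci[0],
                "ci_upper": e.ci[1],
                "pval": e.pval,
                "q": np.nan,
                "q_pval": np.nan,
            }
        )
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    mode = "a" if append and Path(path).exists() else "w"
    df.to_csv(path, sep="\t", index=False, mode=mode, header=(mode == "w"))


def read_mr_table(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_mr_table` output."""
    return pd.read_csv(path, sep="\t")
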