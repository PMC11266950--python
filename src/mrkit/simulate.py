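"""Synthetic individual-level and summary-level GWAS data.

Generates data with the statistical structure two-sample Mendelian
randomization assumes: Hardy–Weinberg genotypes at given allele frequencies,
a continuous exposure built so the instruments explain a target fraction of
its variance (then rank-based inverse-normal transformed, as hormone
phenotypes typically are before GWAS), and binary outcomes from a logistic
model calibrated to a target prevalence.  A two-sample driver draws exposure
and outcome samples with a configurable shared fraction of individuals and an
optional shared confounder, which together reproduce the weak-instrument /
sample-overlap bias mechanism.

Defaults mirror the anti-Müllerian-hormone (AMH) study conditions this
package's verification suite is built around: four instruments jointly
explaining R² = 0.0147 of the exposure, an exposure GWAS of 7,049 women, and
case/control outcome GWASs drawn from separate samples (overlap 0).
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, replace
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from . import mr
from .scan import GenotypeMatrix
from .sumstats import VariantAssociation

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "inverse_normal_transform",
    "simulate_exposure",
    "simulate_binary_outcome",
    "compute_sumstats",
    "simulate_two_sample",
]

_DEFAULT_EAFS = (0.1, 0.2, 0.3, 0.4)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic two-sample generator.

    Defaults are the conditions of the AMH application: k = 4 instruments
    with equal variance shares, total exposure variance explained 0.0147, an
    exposure sample of 7,049, a stroke-sized outcome sample (17,541 at case
    fraction 0.267), no causal effect, no confounding and no sample overlap.
    """

    n_exposure_sample: int = 7049
    n_outcome_sample: int = 17541
    eafs: tuple[float, ...] = _DEFAULT_EAFS
    r2_target: float = 0.0147
    variance_shares: tuple[float, ...] | None = None
    causal_log_or: float = 0.0
    prevalence: float = 0.267
    overlap_fraction: float = 0.0
    confounder_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exposure_sample < 1 or self.n_outcome_sample < 1:
            raise ValueError("sample sizes must be positive")
        if any(not (0.0 < f < 1.0) for f in self.eafs):
            raise ValueError("allele frequencies must lie in (0, 1)")
        if not (0.0 < self.r2_target < 1.0):
            raise ValueError("r2_target must lie in (0, 1)")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1]")
        shares = self.variance_shares
        if shares is not None:
            if len(shares) != len(self.eafs):
                raise ValueError("one variance share per variant required")
            if any(s <= 0 for s in shares):
                raise ValueError("variance shares must be positive")
            if not math.isclose(sum(shares), 1.0, abs_tol=1e-8):
                raise ValueError(f"variance shares must sum to 1, got {sum(shares)}")

    @property
    def k(self) -> int:
        return len(self.eafs)

    @property
    def shares(self) -> tuple[float, ...]:
        if self.variance_shares is not None:
            return self.variance_shares
        return tuple(1.0 / self.k for _ in self.eafs)

    def per_variant_betas(self) -> np.ndarray:
        """Effect sizes on the unit-variance exposure scale.

        Scaled so that ``sum_i 2 eaf_i (1 - eaf_i) beta_i^2 = r2_target``.
        """
        eafs = np.asarray(self.eafs)
        shares = np.asarray(self.shares)
        var_g = 2.0 * eafs * (1.0 - eafs)
        return np.sqrt(self.r2_target * shares / var_g)


def _rsids(k: int) -> list[str]:
    return [f"rs_sim{i + 1}" for i in range(k)]


def simulate_genotypes(
    n: int, eafs: Sequence[float], seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Hardy–Weinberg genotypes: dosage = sum of two Bernoulli(eaf) draws."""
    if n < 1:
        raise ValueError("n must be >= 1")
    eafs = np.asarray(eafs, dtype=float)
    if np.any((eafs <= 0) | (eafs >= 1)):
        raise ValueError("allele frequencies must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dosages = rng.binomial(2, eafs, size=(n, eafs.size)).astype(float)
    rsids = _rsids(eafs.size)
    return GenotypeMatrix(
        dosages=pd.DataFrame(dosages, columns=rsids),
        effect_alleles={r: "A" for r in rsids},
        other_alleles={r: "G" for r in rsids},
    )


def inverse_normal_transform(values: Sequence[float], offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal (Blom) transformation.

    Maps value of rank ``r`` (ties averaged) to
    ``Phi^{-1}((r - offset) / (n + 1 - 2*offset))``; the default offset 3/8
    gives Blom scores.  Rank order is preserved; the output is approximately
    standard normal for continuous input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to rank")
    if np.all(x == x[0]):
        raise ValueError("constant input: all ranks tied")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (x.size + 1.0 - 2.0 * offset))


def simulate_exposure(
    G: GenotypeMatrix,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
    confounder: np.ndarray | None = None,
) -> np.ndarray:
    """Continuous exposure with the configured genetic architecture.

    On the latent scale: ``x = sum_i beta_i g_i + c*u + e`` with noise
    variance chosen so the total (confounder included) is 1; the returned
    phenotype is the rank-based inverse normal transform of the latent
    value, matching how such hormone levels enter GWAS.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    betas = config.per_variant_betas()
    dosages = G.dosages.to_numpy(dtype=float)
    genetic = dosages @ betas
    c = config.confounder_strength
    noise_var = 1.0 - config.r2_target - c**2
    if noise_var <= 0:
        raise ValueError("r2_target plus confounder variance must stay below 1")
    latent = genetic + math.sqrt(noise_var) * rng.standard_normal(G.n)
    if confounder is not None:
        latent = latent + c * confounder
    return inverse_normal_transform(latent)


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept alpha with mean(expit(alpha + eta)) = prevalence, by Brent."""

    def excess(alpha: float) -> float:
        return float(np.mean(special.expit(alpha + eta))) - prevalence

    return float(optimize.brentq(excess, -50.0, 50.0, xtol=1e-10))


def simulate_binary_outcome(
    exposure: np.ndarray,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
    confounder: np.ndarray | None = None,
) -> np.ndarray:
    """Binary outcome from a logistic model at the configured prevalence.

    ``P(y=1) = expit(alpha + causal_log_or * x [+ c * u])`` with ``alpha``
    solved numerically so the expected case fraction equals ``prevalence``.
    """
    exposure = np.asarray(exposure, dtype=float)
    if not np.all(np.isfinite(exposure)):
        raise ValueError("exposure contains non-finite values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eta = config.causal_log_or * exposure
    if confounder is not None:
        eta = eta + config.confounder_strength * confounder
    alpha = _solve_intercept(eta, config.prevalence)
    return (rng.random(exposure.size) < special.expit(alpha + eta)).astype(int)


def _linear_marginal(g: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Simple-regression slope and SE of y on one dosage column."""
    n = g.size
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = float(gc @ gc)
    beta = float(gc @ yc) / sxx
    resid = yc - beta * gc
    sigma2 = float(resid @ resid) / (n - 2)
    return beta, math.sqrt(sigma2 / sxx)


def compute_sumstats(
    G: GenotypeMatrix,
    phenotype: np.ndarray,
    family: str = "linear",
    trait: str = "trait",
    n_label: int | None = None,
) -> list[VariantAssociation]:
    """Per-variant marginal GWAS on the simulated sample.

    ``family="linear"`` fits ordinary least squares per variant (closed
    form); ``family="logistic"`` fits a per-variant logistic model and
    reports effects on the log-odds scale.
    """
    y = np.asarray(phenotype, dtype=float)
    records = []
    scale = {"linear": "linear", "logistic": "log_odds"}.get(family)
    if scale is None:
        raise ValueError(f"family must be linear or logistic, got {family!r}")
    for rsid in G.variants:
        g = G.dosages[rsid].to_numpy(dtype=float)
        if family == "linear":
            beta, se = _linear_marginal(g, y)
        else:
            X = np.column_stack([g, np.ones_like(g)])
            fit = sm.Logit(y, X).fit(disp=0)
            beta, se = float(fit.params[0]), float(fit.bse[0])
        pval = float(2.0 * stats.norm.sf(abs(beta / se)))
        records.append(
            VariantAssociation(
                rsid=rsid,
                effect_allele=G.effect_alleles[rsid],
                other_allele=G.other_alleles.get(rsid, "G"),
                beta=beta,
                se=se,
                eaf=float(g.mean() / 2.0),
                pval=max(pval, 5e-324),
                n=n_label or G.n,
                trait=trait,
                scale=scale,
            )
        )
    return records


def simulate_two_sample(
    config: SimConfig,
) -> tuple[list[VariantAssociation], list[VariantAssociation], dict[str, Any]]:
    """Draw a full two-sample MR dataset and its generating truth.

    A pooled population of ``n_exposure + n_outcome - n_shared`` individuals
    is simulated once; the exposure GWAS uses the first ``n_exposure`` of
    them and the outcome GWAS the last ``n_outcome``, so ``overlap_fraction``
    of the outcome sample is shared with the exposure sample.  The truth
    record carries the causal effect, the realized instrument R² in the
    exposure sample, and the corresponding F-statistic.
    """
    rng = np.random.default_rng(config.seed)
    n_exp, n_out = config.n_exposure_sample, config.n_outcome_sample
    n_shared = int(round(config.overlap_fraction * min(n_exp, n_out)))
    n_total = n_exp + n_out - n_shared

    G = simulate_genotypes(n_total, config.eafs, rng)
    confounder = rng.standard_normal(n_total) if config.confounder_strength else None
    # Latent exposure for everyone; each sample INT-transforms its own slice,
    # as separate GWAS cohorts would.
    betas = config.per_variant_betas()
    dosages = G.dosages.to_numpy(dtype=float)
    c = config.confounder_strength
    noise_var = 1.0 - config.r2_target - c**2
    if noise_var <= 0:
        raise ValueError("r2_target plus confounder variance must stay below 1")
    latent = dosages @ betas + math.sqrt(noise_var) * rng.standard_normal(n_total)
    if confounder is not None:
        latent = latent + c * confounder

    exp_idx = np.arange(0, n_exp)
    out_idx = np.arange(n_total - n_out, n_total)

    x_exp = inverse_normal_transform(latent[exp_idx])
    G_exp = GenotypeMatrix(
        G.dosages.iloc[exp_idx].reset_index(drop=True),
        G.effect_alleles,
        G.other_alleles,
    )
    exposure_stats = [
        replace(rec, scale="inverse_normal")
        for rec in compute_sumstats(G_exp, x_exp, family="linear", trait="exposure")
    ]

    x_out = inverse_normal_transform(latent[out_idx])
    conf_out = confounder[out_idx] if confounder is not None else None
    y = simulate_binary_outcome(x_out, config, rng, conf_out)
    G_out = GenotypeMatrix(
        G.dosages.iloc[out_idx].reset_index(drop=True),
        G.effect_alleles,
        G.other_alleles,
    )
    outcome_stats = compute_sumstats(G_out, y.astype(float), family="logistic", trait="outcome")

    # Realized instrument strength in the exposure sample.
    X = np.column_stack([G_exp.dosages.to_numpy(dtype=float), np.ones(n_exp)])
    fit = sm.OLS(x_exp, X).fit()
    r2_real = float(fit.rsquared)
    f_real = mr.f_statistic(r2_real, n_exp, config.k).value if 0 < r2_real < 1 else float("nan")

    truth = {
        "seed": config.seed,
        "causal_log_or": config.causal_log_or,
        "r2_target": config.r2_target,
        "r2_realized": r2_real,
        "f_realized": f_real,
        "n_exposure": n_exp,
        "n_outcome": n_out,
        "n_shared": n_shared,
        "prevalence_target": config.prevalence,
        "case_fraction_realized": float(np.mean(y)),
        "per_variant_betas": betas.tolist(),
        "eafs": list(config.eafs),
    }
    return exposure_stats, outcome_stats, truth
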