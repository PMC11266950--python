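"""Weighted genetic-risk-score construction and per-trait association scans.

Horizontal pleiotropy — instruments affecting the outcome through pathways
that bypass the exposure — is the central threat to Mendelian randomization.
A standard diagnostic is to regress a panel of candidate confounders and
intermediate traits on each instrument and on their weighted genetic risk
score (GRS), align the resulting z-scores with the exposure-increasing
direction, and flag associations surviving a Benjamini–Hochberg false
discovery rate threshold.  This module provides that machinery and the
heatmap-matrix export used to visualise it.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "GenotypeMatrix",
    "TraitTable",
    "ScanResult",
    "ScanFrame",
    "build_grs",
    "align_weights",
    "associate_trait",
    "bh_fdr",
    "run_scan",
    "write_scan_tables",
    "plot_heatmap",
]

GRS_LABEL = "GRS"


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with effect-allele labels.

    ``dosages`` is a DataFrame (rows = samples, columns = variant rsids) of
    effect-allele dosages in [0, 2]; ``effect_alleles`` maps each rsid to the
    allele the dosage counts; ``other_alleles`` to its partner.
    """

    dosages: pd.DataFrame
    effect_alleles: dict[str, str]
    other_alleles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.dosages.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate variant labels in genotype matrix")
        vals = self.dosages.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
            raise ValueError("dosages must lie in [0, 2]")
        missing = [c for c in cols if c not in self.effect_alleles]
        if missing:
            raise ValueError(f"variants without an effect-allele label: {missing}")

    @property
    def variants(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]


@dataclass
class TraitTable:
    """Per-individual trait values plus per-trait model family.

    ``families`` maps each trait label to ``continuous`` (linear model) or
    ``binary`` (logistic model, values coded 0/1).
    """

    values: pd.DataFrame
    families: dict[str, str]

    def __post_init__(self) -> None:
        for trait in self.values.columns:
            fam = self.families.get(trait)
            if fam not in ("continuous", "binary"):
                raise ValueError(f"trait {trait!r}: family must be continuous or binary")
            if fam == "binary":
                vals = self.values[trait].dropna().unique()
                if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
                    raise ValueError(f"binary trait {trait!r} must be coded 0/1")

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class ScanResult:
    """One predictor-by-trait association cell."""

    predictor: str
    trait: str
    beta: float
    se: float
    z_aligned: float
    pval: float
    qval: float | None = None
    significant: bool | None = None
    converged: bool = True


def build_grs(
    G: GenotypeMatrix,
    weights: Mapping[str, float],
    weight_alleles: Mapping[str, str] | None = None,
) -> pd.Series:
    """Weighted genetic risk score: ``score_j = sum_i w_i g_ij``.

    ``weights`` are per-variant exposure effect sizes.  If ``weight_alleles``
    is given and a weight's allele is the variant's *other* allele, the
    weight is re-expressed on the dosage allele (negated) so the score
    accumulates exposure-increasing alleles consistently; this changes the
    score only by a per-variant constant, which association z-scores do not
    see.  The score is not normalised by the weight sum — scale does not
    affect z-scores either.
    """
    aligned = align_weights(G, weights, weight_alleles)
    score = pd.Series(0.0, index=G.dosages.index)
    for rsid in G.variants:
        score = score + aligned[rsid] * G.dosages[rsid].astype(float)
    return score


def align_weights(
    G: GenotypeMatrix,
    weights: Mapping[str, float],
    weight_alleles: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Express each weight on the dosage (effect) allele of ``G``."""
    missing = [v for v in G.variants if v not in weights]
    if missing:
        raise ValueError(f"variants without a weight: {missing}")
    aligned: dict[str, float] = {}
    for rsid in G.variants:
        w = float(weights[rsid])
        if weight_alleles is not None:
            allele = weight_alleles[rsid]
            if allele == G.other_alleles.get(rsid):
                w = -w
            elif allele != G.effect_alleles[rsid]:
                raise ValueError(
                    f"{rsid}: weight allele {allele!r} matches neither dosage allele"
                )
        aligned[rsid] = w
    return aligned


def associate_trait(
    y: pd.Series | np.ndarray,
    x: pd.Series | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    family: str = "continuous",
) -> ScanResult:
    """Slope of ``x`` from a linear or logistic model of ``y``, with covariates.

    Returns beta, SE, z = beta/se and a two-sided normal p-value.  A
    non-convergent logistic fit is returned flagged (``converged=False``,
    NaN statistics) rather than raised, so a scan can skip the cell.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        X = np.column_stack([x, covariates])
    else:
        X = x[:, None]
    complete = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[complete], X[complete]
    if y.size < 10:
        raise ValueError(f"need at least 10 complete cases, got {y.size}")
    if np.var(X[:, 0]) == 0:
        raise ValueError("predictor has zero variance (degenerate design)")
    X = sm.add_constant(X, prepend=False)

    if family == "continuous":
        fit = sm.OLS(y, X).fit()
        converged = True
    elif family == "binary":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            converged = bool(fit.mle_retvals.get("converged", True))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            converged = False
            fit = None
    else:
        raise ValueError(f"family must be continuous or binary, got {family!r}")

    if not converged or fit is None:
        return ScanResult(".", ".", np.nan, np.nan, np.nan, np.nan, converged=False)
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    if se == 0 or not np.isfinite(se):
        raise ValueError("degenerate fit: zero or non-finite standard error")
    z = beta / se
    pval = float(2.0 * _norm_sf(abs(z)))
    return ScanResult(".", ".", beta, se, z, pval, converged=True)


def _norm_sf(z: float) -> float:
    from scipy import stats

    return stats.norm.sf(z)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the ascending-sorted p-values,
    capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass
class ScanFrame:
    """Full scan output: long-form results plus heatmap-ready matrices.

    ``z`` is the predictors x traits matrix of direction-aligned z-scores
    (NaN for failed cells); ``q`` and ``flags`` are companion matrices of
    FDR q-values and significance indicators.
    """

    results: pd.DataFrame
    z: pd.DataFrame
    q: pd.DataFrame
    flags: pd.DataFrame
    alpha: float


def run_scan(
    G: GenotypeMatrix,
    traits: TraitTable,
    weights: Mapping[str, float],
    covariates: pd.DataFrame | np.ndarray | None = None,
    weight_alleles: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    fdr_scope: str = "global",
    include_grs: bool = True,
) -> ScanFrame:
    """Associate every variant (and the GRS) with every trait.

    z-scores are aligned with the exposure-increasing direction of each
    predictor: a variant whose exposure weight is negative has its z negated
    (equivalently, its exposure-increasing allele is the other allele); the
    GRS is exposure-increasing by construction.  FDR is applied across all
    cells jointly (``fdr_scope="global"``) or within each predictor's row
    (``"per_predictor"``); cells that failed to converge are excluded.
    """
    if fdr_scope not in ("global", "per_predictor"):
        raise ValueError(f"fdr_scope must be global or per_predictor, got {fdr_scope!r}")
    aligned = align_weights(G, weights, weight_alleles)
    predictors: list[tuple[str, pd.Series, float]] = []
    for rsid in G.variants:
        align = 1.0 if aligned[rsid] >= 0 else -1.0
        predictors.append((rsid, G.dosages[rsid].astype(float), align))
    if include_grs:
        grs = build_grs(G, weights, weight_alleles)
        predictors.append((GRS_LABEL, grs, 1.0))

    rows = []
    for label, x, align in predictors:
        for trait in traits.traits:
            fam = traits.families[trait]
            try:
                res = associate_trait(traits.values[trait], x, covariates, fam)
            except ValueError:
                res = ScanResult(label, trait, np.nan, np.nan, np.nan, np.nan,
                                 converged=False)
            rows.append(
                {
                    "predictor": label,
                    "trait": trait,
                    "beta": res.beta,
                    "se": res.se,
                    "z_aligned": align * res.beta / res.se if res.converged else np.nan,
                    "pval": res.pval,
                    "converged": res.converged,
                }
            )
    df = pd.DataFrame(rows)

    df["qval"] = np.nan
    ok = df["converged"] & np.isfinite(df["pval"])
    if fdr_scope == "global":
        if ok.any():
            df.loc[ok, "qval"] = bh_fdr(df.loc[ok, "pval"].to_numpy())
    else:
        for label in df["predictor"].unique():
            sel = ok & (df["predictor"] == label)
            if sel.any():
                df.loc[sel, "qval"] = bh_fdr(df.loc[sel, "pval"].to_numpy())
    df["significant"] = df["qval"] < alpha

    order = [p[0] for p in predictors]
    z = df.pivot(index="predictor", columns="trait", values="z_aligned").reindex(
        index=order, columns=traits.traits
    )
    q = df.pivot(index="predictor", columns="trait", values="qval").reindex(
        index=order, columns=traits.traits
    )
    flags = q < alpha
    return ScanFrame(df, z, q, flags, alpha)


def write_scan_tables(scan: ScanFrame, prefix: str | Path) -> None:
    """Write the z matrix and the long-form p/q/flag table as TSV."""
    prefix = Path(prefix)
    scan.z.to_csv(prefix.with_suffix(".z.tsv"), sep="\t")
    scan.results.to_csv(prefix.with_suffix(".results.tsv"), sep="\t", index=False)


def plot_heatmap(scan: ScanFrame, path: str | Path) -> None:
    """Render the aligned z-score matrix as a heatmap image (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = scan.z
    fig, ax = plt.subplots(
        figsize=(max(6, 0.3 * z.shape[1]), max(3, 0.5 * z.shape[0]))
    )
    vmax = np.nanmax(np.abs(z.to_numpy())) or 1.0
    im = ax.imshow(z.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(z.shape[1]), z.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(z.shape[0]), z.index, fontsize=8)
    for (i, j), sig in np.ndenumerate(scan.flags.to_numpy()):
        if sig:
            ax.text(j, i, "*", ha="center", va="center")
    fig.colorbar(im, ax=ax, label="aligned z")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
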