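"""GRS construction, trait association and FDR control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mrkit.scan import (
    GenotypeMatrix,
    TraitTable,
    associate_trait,
    bh_fdr,
    build_grs,
    run_scan,
    write_scan_tables,
)
from mrkit.simulate import simulate_genotypes


def make_g(dosages, effect_alleles=None, other_alleles=None):
    df = pd.DataFrame(dosages, columns=[f"rs{i}" for i in range(np.shape(dosages)[1])])
    ea = effect_alleles or {c: "A" for c in df.columns}
    oa = other_alleles or {c: "G" for c in df.columns}
    return GenotypeMatrix(df, ea, oa)


# ----------------------------------------------------------------------- GRS


def test_grs_is_weighted_dosage_sum():
    G = make_g([[0, 1, 2, 1]])
    score = build_grs(G, {f"rs{i}": 1.0 for i in range(4)})
    assert score.iloc[0] == pytest.approx(4.0)


def test_grs_single_variant_scales_dosage():
    G = make_g([[2.0], [1.0], [0.0]])
    score = build_grs(G, {"rs0": 0.25})
    assert list(score) == [0.5, 0.25, 0.0]


def test_grs_missing_weight_errors():
    with pytest.raises(ValueError, match="without a weight"):
        build_grs(make_g([[1, 1]]), {"rs0": 1.0})


def test_grs_allele_reflection_only_shifts_scores(rng):
    """Negating one weight while reflecting its dosage column (g -> 2 - g)
    shifts all scores by a constant, so association z is unchanged."""
    G = simulate_genotypes(500, (0.2, 0.4), rng)
    weights = {"rs_sim1": 0.3, "rs_sim2": -0.2}
    s1 = build_grs(G, weights)
    reflected = G.dosages.copy()
    reflected["rs_sim2"] = 2.0 - reflected["rs_sim2"]
    G2 = GenotypeMatrix(reflected, {"rs_sim1": "A", "rs_sim2": "G"},
                        {"rs_sim1": "G", "rs_sim2": "A"})
    s2 = build_grs(G2, {"rs_sim1": 0.3, "rs_sim2": 0.2})
    diff = s2 - s1
    assert np.allclose(diff, diff.iloc[0])
    y = 0.5 * s1.to_numpy() + rng.standard_normal(500)
    r1 = associate_trait(y, s1, family="continuous")
    r2 = associate_trait(y, s2, family="continuous")
    assert r1.beta / r1.se == pytest.approx(r2.beta / r2.se, rel=1e-9)


def test_grs_weight_stated_on_other_allele_gives_same_z(rng):
    """A weight recorded for the other allele is re-expressed on the dosage
    allele; z against any trait is identical either way."""
    G = simulate_genotypes(500, (0.2, 0.4), rng)
    s1 = build_grs(G, {"rs_sim1": 0.3, "rs_sim2": -0.2})
    # same physical weights, rs_sim2's stated on the G (other) allele
    s2 = build_grs(G, {"rs_sim1": 0.3, "rs_sim2": 0.2},
                   weight_alleles={"rs_sim1": "A", "rs_sim2": "G"})
    y = 0.5 * s1.to_numpy() + rng.standard_normal(500)
    r1 = associate_trait(y, s1, family="continuous")
    r2 = associate_trait(y, s2, family="continuous")
    assert r1.beta / r1.se == pytest.approx(r2.beta / r2.se, rel=1e-9)


def test_genotype_matrix_invariants():
    with pytest.raises(ValueError, match="duplicate"):
        GenotypeMatrix(
            pd.DataFrame([[1, 1]], columns=["rs1", "rs1"]), {"rs1": "A"}
        )
    with pytest.raises(ValueError, match="dosages"):
        make_g([[3.0]])


# ---------------------------------------------------------------- association


def test_linear_association_recovers_strong_slope(rng):
    x = rng.standard_normal(200)
    y = 2.0 * x + 1e-8 * rng.standard_normal(200)
    res = associate_trait(y, x, family="continuous")
    assert res.beta == pytest.approx(2.0, abs=1e-6)
    assert abs(res.beta / res.se) > 1e6


def test_logistic_association_recovers_slope(rng):
    from scipy.special import expit

    g = rng.binomial(2, 0.3, size=20_000).astype(float)
    y = (rng.random(20_000) < expit(-1.0 + 0.5 * g)).astype(float)
    res = associate_trait(y, g, family="binary")
    assert res.beta == pytest.approx(0.5, abs=3 * res.se)


def test_null_z_scores_are_standard_normal(rng):
    zs = []
    for _ in range(1000):
        x = rng.standard_normal(60)
        y = rng.standard_normal(60)
        r = associate_trait(y, x, family="continuous")
        zs.append(r.beta / r.se)
    zs = np.array(zs)
    assert abs(zs.mean()) < 3 / np.sqrt(1000)
    assert np.var(zs) == pytest.approx(1.0, abs=0.15)


def test_association_degenerate_inputs():
    with pytest.raises(ValueError, match="zero variance"):
        associate_trait(np.arange(20.0), np.ones(20))
    with pytest.raises(ValueError, match="complete cases"):
        associate_trait(np.arange(5.0), np.arange(5.0))


def test_covariate_adjustment_changes_slope(rng):
    c = rng.standard_normal(500)
    x = c + 0.1 * rng.standard_normal(500)
    y = c + rng.standard_normal(500)
    raw = associate_trait(y, x, family="continuous")
    adj = associate_trait(y, x, covariates=c, family="continuous")
    assert abs(adj.beta) < abs(raw.beta)


# ----------------------------------------------------------------------- FDR


def _bh_bruteforce(pvals):
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        i = rank_pos + 1
        q[idx] = min(
            min(p[order[j]] * m / (j + 1) for j in range(rank_pos, m)), 1.0
        )
    return q


def test_bh_worked_examples():
    assert bh_fdr([0.03]) == pytest.approx([0.03])
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_fdr([0.001, 1.0]) == pytest.approx([0.002, 1.0])


@given(arrays(float, st.integers(1, 30), elements=st.floats(0, 1)))
def test_bh_matches_bruteforce_stepup(p):
    assert bh_fdr(p) == pytest.approx(_bh_bruteforce(p), abs=1e-12)


@given(arrays(float, st.integers(2, 15), elements=st.floats(0, 1)),
       st.randoms(use_true_random=False))
def test_bh_permutation_invariance_and_qp_ordering(p, rand):
    q = bh_fdr(p)
    assert np.all(q >= p - 1e-15)
    idx = list(range(p.size))
    rand.shuffle(idx)
    assert bh_fdr(p[idx]) == pytest.approx(q[np.array(idx)])


def test_bh_monotone_in_single_p():
    p = np.array([0.01, 0.2, 0.5, 0.9])
    q = bh_fdr(p)
    p2 = p.copy()
    p2[1] = 0.4
    assert np.all(bh_fdr(p2) >= q - 1e-15)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------- scan


@pytest.fixture
def planted_scan(rng):
    n = 4000
    G = simulate_genotypes(n, (0.1, 0.2, 0.3, 0.4), rng)
    weights = {v: w for v, w in zip(G.variants, (0.1, 0.12, 0.09, 0.11))}
    grs = build_grs(G, weights)
    values = {"signal": 2.0 * grs.to_numpy() + rng.standard_normal(n)}
    for i in range(5):
        values[f"null{i}"] = rng.standard_normal(n)
    values["null_binary"] = rng.integers(0, 2, n).astype(float)
    traits = TraitTable(
        pd.DataFrame(values),
        {t: ("binary" if t == "null_binary" else "continuous") for t in values},
    )
    return G, traits, weights


def test_scan_flags_planted_signal(planted_scan):
    """The planted-signal column lights up for every predictor; flagged null
    cells are at most the occasional chance discovery BH permits."""
    G, traits, weights = planted_scan
    scan = run_scan(G, traits, weights)
    assert scan.flags.loc[:, "signal"].all()
    assert scan.q.loc["GRS", "signal"] == scan.q.to_numpy().min()
    null_cols = [t for t in traits.traits if t != "signal"]
    assert scan.flags.loc[:, null_cols].to_numpy().sum() <= 2
    assert set(scan.z.index) == set(G.variants) | {"GRS"}


def test_scan_qvals_dominate_pvals_and_flags_match_threshold(planted_scan):
    G, traits, weights = planted_scan
    scan = run_scan(G, traits, weights, alpha=0.05)
    ok = scan.results.dropna(subset=["qval"])
    assert np.all(ok["qval"] >= ok["pval"] - 1e-15)
    assert (ok["significant"] == (ok["qval"] < 0.05)).all()


def test_scan_z_invariant_to_effect_allele_relabeling(planted_scan):
    """Recoding one variant's dosages to the other allele (g -> 2 - g) with
    the weight expressed on that allele leaves the aligned z matrix fixed."""
    G, traits, weights = planted_scan
    base = run_scan(G, traits, weights)
    flipped_dosages = G.dosages.copy()
    flipped_dosages["rs_sim1"] = 2.0 - flipped_dosages["rs_sim1"]
    G2 = GenotypeMatrix(
        flipped_dosages,
        {**G.effect_alleles, "rs_sim1": "G"},
        {**G.other_alleles, "rs_sim1": "A"},
    )
    alleles = {v: "A" for v in G.variants}  # weights all stated on the A allele
    other = run_scan(G2, traits, weights, weight_alleles=alleles)
    np.testing.assert_allclose(base.z.to_numpy(), other.z.to_numpy(), atol=1e-9)


def test_scan_degenerate_single_cell_reduces_to_associate(rng):
    G = simulate_genotypes(300, (0.3,), rng)
    y = 0.4 * G.dosages["rs_sim1"].to_numpy() + rng.standard_normal(300)
    traits = TraitTable(pd.DataFrame({"y": y}), {"y": "continuous"})
    scan = run_scan(G, traits, {"rs_sim1": 0.1}, include_grs=False)
    direct = associate_trait(y, G.dosages["rs_sim1"], family="continuous")
    cell = scan.results.iloc[0]
    assert cell["beta"] == pytest.approx(direct.beta)
    assert cell["qval"] == pytest.approx(direct.pval)  # m = 1 identity


def test_scan_failed_cells_missing_not_zero(rng):
    G = simulate_genotypes(300, (0.3,), rng)
    traits = TraitTable(
        pd.DataFrame({"flat": np.zeros(300), "ok": rng.standard_normal(300)}),
        {"flat": "continuous", "ok": "continuous"},
    )
    # zero-variance *predictor* cell: constant dosage column
    G2 = GenotypeMatrix(
        pd.DataFrame({"rs_sim1": G.dosages["rs_sim1"], "rs_const": np.ones(300)}),
        {"rs_sim1": "A", "rs_const": "A"},
        {"rs_sim1": "G", "rs_const": "G"},
    )
    scan = run_scan(G2, traits, {"rs_sim1": 0.1, "rs_const": 0.1}, include_grs=False)
    assert np.isnan(scan.z.loc["rs_const", "ok"])
    assert not scan.flags.loc["rs_const", "ok"]


def test_scan_fdr_scope_modes_differ(planted_scan):
    G, traits, weights = planted_scan
    glob = run_scan(G, traits, weights, fdr_scope="global")
    per = run_scan(G, traits, weights, fdr_scope="per_predictor")
    assert glob.results["pval"].equals(per.results["pval"])
    assert not np.allclose(
        glob.results["qval"].to_numpy(), per.results["qval"].to_numpy(),
        equal_nan=True,
    )


def test_scan_null_family_error_rate(rng):
    """Under a global null the chance that any cell is flagged is about the
    FDR level (Simes-test behaviour of step-up BH under independence)."""
    reps, hits = 400, 0
    for _ in range(reps):
        n = 150
        G = simulate_genotypes(n, (0.3, 0.4), rng)
        traits = TraitTable(
            pd.DataFrame({f"t{i}": rng.standard_normal(n) for i in range(4)}),
            {f"t{i}": "continuous" for i in range(4)},
        )
        scan = run_scan(G, traits, {"rs_sim1": 0.1, "rs_sim2": 0.1},
                        include_grs=False)
        hits += bool(scan.flags.to_numpy().any())
    rate = hits / reps
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) <= 3 * se


def test_write_scan_tables(tmp_path, planted_scan):
    G, traits, weights = planted_scan
    scan = run_scan(G, traits, weights)
    write_scan_tables(scan, tmp_path / "scan")
    z = pd.read_csv(tmp_path / "scan.z.tsv", sep="\t", index_col=0)
    assert z.shape == scan.z.shape
    res = pd.read_csv(tmp_path / "scan.results.tsv", sep="\t")
    assert len(res) == scan.z.size
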