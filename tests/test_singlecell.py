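"""Cell QC, DM statistic, jackpot/cycle scoring, correlation and cis tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lincterm.singlecell import (assign_cell_cycle, cell_size_factors,
                                 cis_coexpression, correlation_screen,
                                 dm_statistic, jackpot_score, qc_cells,
                                 standardize_profiles, variable_genes_pca)


def nb_counts(rng, mu, disp, n_cells):
    """Gamma-Poisson draw: mean mu, CV^2 = 1/mu + disp."""
    mu = np.asarray(mu, dtype=float)[:, None] * np.ones(n_cells)
    lam = rng.gamma(1.0 / disp, mu * disp)
    return rng.poisson(lam).astype(float)


# ------------------------------------------------------------------ cell QC

def test_qc_thresholds():
    rec = pd.DataFrame({
        "mapped_reads": [0.4e6, 2e6, 2e6, 2e6],
        "mito_fraction": [0.02, 0.12, 0.02, 0.05],
        "capture_annotation": ["ok", "ok", "doublet", "ok"],
    }, index=["low_reads", "high_mito", "doublet", "clean"])
    out = qc_cells(rec)
    assert not out.loc["low_reads", "passed"]
    assert "mapped_reads" in out.loc["low_reads", "fail_reasons"]
    assert not out.loc["high_mito", "passed"]
    assert not out.loc["doublet", "passed"]
    assert out.loc["clean", "passed"]


def test_boundary_cells_pass():
    rec = pd.DataFrame({"mapped_reads": [0.5e6], "mito_fraction": [0.10]},
                       index=["edge"])
    assert qc_cells(rec)["passed"].all()


def test_identical_cells_get_unit_size_factors():
    counts = pd.DataFrame(np.tile([[10], [40], [90]], (1, 5)).astype(float))
    assert np.allclose(cell_size_factors(counts).size_factors, 1.0)


# ------------------------------------------------------------ variable genes

def test_planted_variable_genes_dominate_pc1():
    rng = np.random.default_rng(0)
    n_genes, n_cells = 400, 100
    X = rng.normal(10, 0.1, (n_genes, n_cells))
    planted = rng.choice(n_genes, 10, replace=False)
    factor = rng.normal(0, 4, n_cells)
    X[planted] += factor  # shared high-variance direction
    mat = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)])
    got = variable_genes_pca(mat, n_pcs=3, top_per_pc=10, log_transform=False)
    assert set(f"g{i}" for i in planted) <= set(got)
    assert len(got) <= 30


def test_variable_gene_set_invariant_to_cell_order():
    rng = np.random.default_rng(1)
    mat = pd.DataFrame(rng.poisson(20, (350, 60)).astype(float),
                       index=[f"g{i}" for i in range(350)])
    a = variable_genes_pca(mat, n_pcs=2, top_per_pc=50)
    perm = rng.permutation(mat.shape[1])
    b = variable_genes_pca(mat.iloc[:, perm], n_pcs=2, top_per_pc=50)
    assert a == b


def test_fewer_genes_than_top_returns_all_with_warning():
    mat = pd.DataFrame(np.random.default_rng(0).poisson(5, (20, 30)).astype(float),
                       index=[f"g{i}" for i in range(20)])
    assert set(variable_genes_pca(mat, top_per_pc=300)) == set(mat.index)


# ------------------------------------------------------------- DM statistic

def test_gene_on_its_running_median_has_zero_dm():
    rng = np.random.default_rng(2)
    mat = pd.DataFrame(nb_counts(rng, np.full(500, 10.0), 0.2, 300),
                       index=[f"g{i}" for i in range(500)])
    dm = dm_statistic(mat)
    # a gene whose log CV^2 equals its window median by construction
    mid = dm.dropna()
    zeros = (mid["dm"].abs() < 1e-12).sum()
    assert zeros >= 1  # window medians hit at least one member exactly


def test_null_simulation_median_dm_near_zero():
    rng = np.random.default_rng(3)
    mu = np.exp(rng.uniform(np.log(1), np.log(50), 2000))
    mat = pd.DataFrame(nb_counts(rng, mu, 0.2, 200),
                       index=[f"g{i}" for i in range(2000)])
    dm = dm_statistic(mat)
    assert abs(np.nanmedian(dm["dm"])) < 0.05


def test_planted_overdispersed_genes_recovered_in_top_decile():
    rng = np.random.default_rng(4)
    n = 2000
    mu = np.exp(rng.uniform(np.log(5), np.log(50), n))
    disp = np.full(n, 0.2)
    planted = rng.choice(n, 100, replace=False)
    disp[planted] = 1.0  # 5x overdispersion
    lam = rng.gamma(1 / disp[:, None], (mu[:, None] * np.ones(400)) * disp[:, None])
    mat = pd.DataFrame(rng.poisson(lam).astype(float),
                       index=[f"g{i}" for i in range(n)])
    dm = dm_statistic(mat)
    top = set(dm["dm"].nlargest(int(len(dm) * 0.1)).index)
    recall = len(top & {f"g{i}" for i in planted}) / 100
    assert recall > 0.9


def test_dm_invariant_to_global_rescaling():
    rng = np.random.default_rng(5)
    mat = pd.DataFrame(nb_counts(rng, np.full(300, 20.0), 0.3, 150),
                       index=[f"g{i}" for i in range(300)])
    a = dm_statistic(mat)["dm"]
    # power-of-two factors keep the rescaling exact in floating point, so
    # the mathematically exact invariance is not blurred by rounding ties
    for c in (8.0, 0.25):
        b = dm_statistic(mat * c)["dm"]
        assert np.allclose(a.dropna(), b.dropna(), atol=1e-9)


def test_length_bins_change_expected_but_respect_window(caplog):
    rng = np.random.default_rng(6)
    mat = pd.DataFrame(nb_counts(rng, np.full(90, 10.0), 0.2, 100),
                       index=[f"g{i}" for i in range(90)])
    lengths = pd.Series(rng.integers(500, 5000, 90), index=mat.index)
    dm = dm_statistic(mat, gene_lengths=lengths, n_length_bins=3, window=50)
    assert dm["dm"].notna().sum() > 0  # shrunk windows still compute


# ---------------------------------------------------------- jackpot / cycle

def test_constant_gene_p90_equals_median():
    mat = pd.DataFrame(np.full((1, 50), 7.0), index=["g"])
    js = jackpot_score(mat)
    assert js.loc["g", "p90"] == js.loc["g", "median"] == 7.0


def test_quantile_oracle_single_jackpot_cell():
    """1 cell at 100 among 99 zeros: median 0 and, with linear
    interpolation at n=100, p90 = 0."""
    x = np.zeros(100)
    x[0] = 100.0
    mat = pd.DataFrame(x[None, :], index=["g"])
    js = jackpot_score(mat)
    assert js.loc["g", "median"] == 0.0
    assert js.loc["g", "p90"] == pytest.approx(np.percentile(x, 90)) == 0.0


def test_jackpot_genes_have_elevated_p90_over_median():
    rng = np.random.default_rng(7)
    normal = nb_counts(rng, np.full(50, 20.0), 0.1, 200)
    jack = nb_counts(rng, np.full(50, 20.0), 2.0, 200)
    mat = pd.DataFrame(np.vstack([normal, jack]),
                       index=[f"n{i}" for i in range(50)] +
                             [f"j{i}" for i in range(50)])
    js = jackpot_score(mat)
    ratio = (js["p90"] + 1) / (js["median"] + 1)
    assert ratio[[f"j{i}" for i in range(50)]].median() > \
        ratio[[f"n{i}" for i in range(50)]].median()


def test_cell_cycle_assignment_and_unassigned():
    mat = pd.DataFrame({
        "pure_g2m": [0.0, 0.0, 5.0, 6.0],
        "pure_g1s": [4.0, 5.0, 0.0, 0.0],
        "silent": [0.0, 0.0, 0.0, 0.0],
    }, index=["mk_g1s_a", "mk_g1s_b", "mk_g2m_a", "mk_g2m_b"])
    panels = {"G1S": ["mk_g1s_a", "mk_g1s_b"], "G2M": ["mk_g2m_a", "mk_g2m_b"]}
    labels = assign_cell_cycle(mat, panels)
    assert labels["pure_g2m"] == "G2M"
    assert labels["pure_g1s"] == "G1S"
    assert labels["silent"] == "unassigned"


def test_two_stage_population_recovered():
    rng = np.random.default_rng(8)
    n_cells = 200
    stage = rng.random(n_cells) < 0.5
    g1s_markers = [f"g1s{i}" for i in range(5)]
    g2m_markers = [f"g2m{i}" for i in range(5)]
    rows = {}
    for g in g1s_markers:
        mu = np.where(stage, 4.0, 16.0)   # 4x fold for G1S cells
        rows[g] = rng.poisson(mu)
    for g in g2m_markers:
        mu = np.where(stage, 16.0, 4.0)
        rows[g] = rng.poisson(mu)
    mat = pd.DataFrame(rows).T.astype(float)
    labels = assign_cell_cycle(mat, {"G1S": g1s_markers, "G2M": g2m_markers})
    truth = np.where(stage, "G2M", "G1S")
    acc = (labels.to_numpy() == truth).mean()
    assert acc > 0.9


# ------------------------------------------------------- correlation screen

def test_null_significant_fraction_bounded():
    rng = np.random.default_rng(9)
    mat = pd.DataFrame(rng.poisson(10, (120, 150)).astype(float),
                       index=[f"g{i}" for i in range(120)])
    lincs = [f"g{i}" for i in range(20)]
    sig = correlation_screen(mat, lincs, fdr=0.05)
    assert len(sig) / (20 * 100) <= 0.05


def test_perfectly_correlated_planted_pair_returned():
    rng = np.random.default_rng(10)
    base = rng.poisson(20, 100).astype(float)
    mat = pd.DataFrame(rng.poisson(10, (40, 100)).astype(float),
                       index=[f"g{i}" for i in range(40)])
    mat.loc["linc"] = base
    mat.loc["partner"] = base  # identical profile
    sig = correlation_screen(mat, ["linc"], fdr=0.05)
    assert (("linc", "partner") in
            set(zip(sig["lincRNA"], sig["gene"])))


def test_sign_symmetry_of_correlation():
    rng = np.random.default_rng(11)
    base = rng.normal(50, 10, 80)
    mat = pd.DataFrame({"c%d" % j: 0.0 for j in range(80)},
                       index=["linc", "pos", "neg"])
    mat.loc["linc"] = base
    mat.loc["pos"] = base + rng.normal(0, 1, 80)
    mat.loc["neg"] = -base + rng.normal(0, 1, 80)
    sig = correlation_screen(mat, ["linc"], mrna_ids=["pos", "neg"], fdr=0.05)
    r = sig.set_index("gene")["coefficient"]
    assert r["pos"] > 0 > r["neg"]
    assert abs(abs(r["pos"]) - abs(r["neg"])) < 0.1


def test_bh_procedure_matches_direct_step_up_rule():
    rng = np.random.default_rng(12)
    for _ in range(20):
        p = rng.uniform(0, 1, 200)
        p[:10] = rng.uniform(0, 1e-4, 10)
        reject, _, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        # direct step-up: largest k with p_(k) <= k/m * alpha
        order = np.argsort(p)
        m = len(p)
        thresh = 0.05 * (np.arange(1, m + 1) / m)
        below = np.nonzero(p[order] <= thresh)[0]
        expect = np.zeros(m, dtype=bool)
        if len(below):
            expect[order[:below.max() + 1]] = True
        assert (reject == expect).all()


# ---------------------------------------------------------- cis co-expression

def _null_matrix(rng, n_genes, n_cells):
    return pd.DataFrame(rng.poisson(8, (n_genes, n_cells)).astype(float),
                        index=[f"g{i}" for i in range(n_genes)])


def _positions(rng, genes, length=10e6):
    return pd.DataFrame({"chrom": "chr1",
                         "mid": np.sort(rng.uniform(0, length, len(genes)))},
                        index=genes)


def test_null_below_threshold_fraction_near_one_percent():
    rng = np.random.default_rng(13)
    mat = _null_matrix(rng, 1500, 150)
    pos = _positions(rng, list(mat.index))
    pairs, bins, thr = cis_coexpression(
        mat, pos, None, near_min=20e3, near_max=400e3,
        null_range=(2e6, 4e6), bin_size=200e3)
    frac = pairs["below_threshold"].mean()
    n = len(pairs)
    se = np.sqrt(0.01 * 0.99 / n)
    assert abs(frac - 0.01) < max(5 * se, 0.005)


def test_pairs_closer_than_20kb_are_excluded():
    rng = np.random.default_rng(14)
    mat = _null_matrix(rng, 500, 80)
    pos = _positions(rng, list(mat.index), length=2e6)
    pairs, _, _ = cis_coexpression(mat, pos, None, near_min=20e3,
                                   near_max=300e3, null_range=(0.5e6, 1.5e6),
                                   bin_size=100e3)
    assert (pairs["genomic_distance"] >= 20e3).all()


def test_planted_shared_factor_pairs_exceed_null_rate():
    rng = np.random.default_rng(15)
    n_genes, n_cells = 800, 150
    mat = _null_matrix(rng, n_genes, n_cells)
    pos = _positions(rng, list(mat.index))
    # plant a shared latent factor into 30 genomically proximal pairs
    mids = pos["mid"].to_numpy()
    planted_pairs = []
    i = 0
    while len(planted_pairs) < 30 and i < n_genes - 1:
        if 20e3 <= mids[i + 1] - mids[i] < 200e3:
            f = np.exp(1.5 * rng.standard_normal(n_cells))
            mat.iloc[i] = rng.poisson(8 * f)
            mat.iloc[i + 1] = rng.poisson(8 * f)
            planted_pairs.append((mat.index[i], mat.index[i + 1]))
            i += 2
        else:
            i += 1
    assert len(planted_pairs) >= 20
    pairs, bins, thr = cis_coexpression(
        mat, pos, None, near_min=20e3, near_max=200e3,
        null_range=(2e6, 4e6), bin_size=200e3)
    keyed = pairs.set_index(["gene_a", "gene_b"])["below_threshold"]
    hit = np.mean([keyed.get(p, False) for p in planted_pairs])
    assert hit > 0.5                               # planted pairs co-expressed
    others = keyed.drop(index=[p for p in planted_pairs if p in keyed.index])
    assert others.mean() < 0.03                    # background stays near 1%


def test_cis_threshold_invariant_to_cell_permutation():
    rng = np.random.default_rng(16)
    mat = _null_matrix(rng, 400, 100)
    pos = _positions(rng, list(mat.index), length=5e6)
    _, _, thr1 = cis_coexpression(mat, pos, None, near_max=400e3,
                                  null_range=(1e6, 3e6))
    perm = mat.iloc[:, rng.permutation(100)]
    _, _, thr2 = cis_coexpression(perm, pos, None, near_max=400e3,
                                  null_range=(1e6, 3e6))
    assert thr1 == pytest.approx(thr2)


def test_too_few_null_pairs_raises():
    rng = np.random.default_rng(17)
    mat = _null_matrix(rng, 50, 60)
    pos = _positions(rng, list(mat.index), length=1e6)
    with pytest.raises(ValueError, match="null pairs"):
        cis_coexpression(mat, pos, None, null_range=(20e6, 40e6))


def test_standardize_drops_constant_genes():
    mat = pd.DataFrame({"c1": [1.0, 5.0], "c2": [1.0, 9.0]},
                       index=["const", "varying"])
    z = standardize_profiles(mat)
    assert list(z.index) == ["varying"]
    assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
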