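"""Score tests: LD r^2 against the direct correlation formula, greedy
clumping against an exhaustive subset oracle, scoring arithmetic and allele
harmonization, and score evaluation."""

import numpy as np
import pandas as pd
import pytest

from amygrs import GRSModel, build_grs, clump, compare_scores, evaluate_grs, ld_r2, score_samples
from amygrs.score import ScoreError
from conftest import make_dataset


def _meta_frame(ids, ps, chrom=None, pos=None, betas=None):
    m = len(ids)
    return pd.DataFrame({
        "variant_id": ids,
        "chrom": chrom if chrom is not None else [1] * m,
        "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
        "effect_allele": ["A"] * m, "other_allele": ["G"] * m,
        "beta": betas if betas is not None else np.ones(m),
        "se": [0.1] * m, "p": ps, "q_stat": 0.0, "tau2": 0.0, "k": 2,
        "directions": ["++"] * m,
    })


# ---------------------------------------------------------------------------
# LD r^2
# ---------------------------------------------------------------------------

def test_ld_r2_identical_and_oracle():
    rng = np.random.default_rng(0)
    x = rng.binomial(2, 0.4, 200).astype(float)
    y = rng.binomial(2, 0.3, 200).astype(float)
    data = make_dataset(np.column_stack([x, x, y]),
                        phenotype=rng.normal(size=200))
    assert ld_r2(data, "v0", "v1") == pytest.approx(1.0, abs=1e-12)
    # direct-formula oracle
    num = np.mean(x * y) - x.mean() * y.mean()
    r2 = (num / (x.std() * y.std())) ** 2
    assert ld_r2(data, "v0", "v2") == pytest.approx(r2, abs=1e-12)


def test_ld_r2_independent_variants_near_zero():
    rng = np.random.default_rng(1)
    X = rng.binomial(2, 0.4, (5000, 40)).astype(float)
    data = make_dataset(X, phenotype=rng.normal(size=5000))
    r2s = [ld_r2(data, f"v{2*j}", f"v{2*j+1}") for j in range(20)]
    assert np.mean(np.array(r2s) < 0.01) >= 0.95


def test_ld_r2_errors():
    rng = np.random.default_rng(2)
    X = np.column_stack([np.full(100, 1.0),
                         rng.binomial(2, 0.3, 100).astype(float)])
    data = make_dataset(X, phenotype=rng.normal(size=100))
    with pytest.raises(ScoreError, match="variance"):
        ld_r2(data, "v0", "v1")
    small = make_dataset(X[:30], phenotype=rng.normal(size=30))
    with pytest.raises(ScoreError, match="complete pairs"):
        ld_r2(small, "v0", "v1")


# ---------------------------------------------------------------------------
# Clumping
# ---------------------------------------------------------------------------

def clump_subset_oracle(p, pos, chrom, r2, r2_max, window):
    """Exhaustive oracle: the unique subset S such that (a) every retained
    variant has no better linked retained variant and (b) every dropped
    variant has a better linked retained variant, under the (p, pos) order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: (p[i], pos[i]))
    rank = {v: i for i, v in enumerate(order)}

    def linked(i, j):
        return (chrom[i] == chrom[j] and abs(pos[i] - pos[j]) <= window
                and r2[i][j] >= r2_max)

    valid = []
    for mask in range(1 << m):
        S = [i for i in range(m) if mask >> i & 1]
        in_S = set(S)
        ok = all(not (linked(i, j) and rank[j] < rank[i])
                 for i in S for j in S if i != j)
        ok = ok and all(any(linked(i, j) and rank[j] < rank[i] for j in in_S)
                        for i in range(m) if i not in in_S)
        if ok:
            valid.append(sorted(S))
    assert len(valid) == 1, f"oracle found {len(valid)} valid subsets"
    return valid[0]


def test_clump_dominance_and_hand_traced_case():
    rng = np.random.default_rng(3)
    x = rng.binomial(2, 0.4, 500).astype(float)
    z = rng.binomial(2, 0.4, 500).astype(float)
    noisy = np.clip(x + (rng.random(500) < 0.3), 0, 2)  # correlated with x
    panel = make_dataset(np.column_stack([x, x, z, noisy]),
                         phenotype=rng.normal(size=500))
    panel.variants["variant_id"] = ["a", "b", "c", "d"]
    panel.variants["pos"] = [1000, 2000, 3000, 1500]

    # two perfectly correlated variants: only the better p survives
    cand = _meta_frame(["a", "b"], [1e-8, 1e-6], pos=[1000, 2000])
    out = clump(cand, panel)
    assert list(out["variant_id"]) == ["a"]

    # r2(1,2)>=cut, r2(1,3)=0, r2(2,3)>=cut via shared construction:
    # p ascending 1,2,3 -> retained {1, 3}
    r2_ab = ld_r2(panel, "a", "d")
    assert r2_ab >= 0.1
    cand = _meta_frame(["a", "d", "c"], [1e-8, 1e-6, 1e-5],
                       pos=[1000, 1500, 3000])
    out = clump(cand, panel)
    assert list(out["variant_id"]) == ["a", "c"]


def test_clump_r2_boundary_inclusive():
    rng = np.random.default_rng(4)
    x = rng.binomial(2, 0.4, 300).astype(float)
    panel = make_dataset(np.column_stack([x, x]), phenotype=rng.normal(size=300))
    cand = _meta_frame(["v0", "v1"], [1e-8, 1e-6])
    # r2 = 1 exactly: removed at r2_max=1.0 (>= semantics)
    out = clump(cand, panel, r2_max=1.0)
    assert list(out["variant_id"]) == ["v0"]


def test_clump_window_respected():
    rng = np.random.default_rng(5)
    x = rng.binomial(2, 0.4, 300).astype(float)
    panel = make_dataset(np.column_stack([x, x]), phenotype=rng.normal(size=300))
    panel.variants["pos"] = [1000, 300_000_000]
    cand = _meta_frame(["v0", "v1"], [1e-8, 1e-6], pos=[1000, 300_000_000])
    out = clump(cand, panel, window_kb=250)
    assert list(out["variant_id"]) == ["v0", "v1"]  # out of window: both kept


def test_clump_absent_candidate_excluded():
    rng = np.random.default_rng(6)
    x = rng.binomial(2, 0.4, 300).astype(float)
    panel = make_dataset(x[:, None], phenotype=rng.normal(size=300))
    cand = _meta_frame(["v0", "ghost"], [1e-8, 1e-9])
    out = clump(cand, panel)
    assert list(out["variant_id"]) == ["v0"]


def test_clump_matches_exhaustive_oracle_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(30):
        m = int(rng.integers(3, 9))
        n = 400
        # random correlation structure via random latent loadings
        W = rng.normal(size=(m, 2))
        corr = W @ W.T + np.diag(rng.uniform(0.5, 2.0, m))
        d = np.sqrt(np.diag(corr))
        corr = corr / d / d[:, None]
        L = np.linalg.cholesky(corr + 1e-9 * np.eye(m))
        Z = rng.standard_normal((n, m)) @ L.T
        X = (Z > rng.uniform(-0.5, 0.5, m)).astype(float) + \
            (rng.standard_normal((n, m)) @ L.T > 0).astype(float)
        panel = make_dataset(X, phenotype=rng.normal(size=n))
        pos = rng.choice(np.arange(1, 400) * 1000, size=m, replace=False)
        chrom = rng.integers(1, 3, m)
        panel.variants["pos"] = pos
        panel.variants["chrom"] = chrom
        p = rng.uniform(0, 1e-5, m)
        cand = _meta_frame([f"v{j}" for j in range(m)], p, chrom=chrom, pos=pos)
        sds = X.std(axis=0)
        if (sds == 0).any():
            continue
        r2 = np.corrcoef(X.T) ** 2
        expected = clump_subset_oracle(p, pos, chrom, r2, 0.1, 250_000)
        out = clump(cand, panel, r2_max=0.1, window_kb=250)
        got = sorted(int(v[1:]) for v in out["variant_id"])
        assert got == expected


# ---------------------------------------------------------------------------
# Model construction and scoring
# ---------------------------------------------------------------------------

def test_build_grs_threshold_and_empty_diagnostic():
    cand = _meta_frame(["a", "b"], [1e-6, 1e-4], betas=[5.0, 1.0])
    model = build_grs(cand, p_threshold=5e-5)
    assert len(model) == 1
    assert model.entries["weight"].iloc[0] == 5.0
    assert model.provenance["p_threshold"] == 5e-5
    with pytest.raises(ScoreError, match="empty GRS"):
        build_grs(_meta_frame(["a"], [0.5]))


def test_score_hand_fixture_and_normalization():
    data = make_dataset(np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]),
                        phenotype=np.zeros(3))
    model = GRSModel(entries=pd.DataFrame({
        "variant_id": ["v0", "v1"], "chrom": [1, 1], "pos": [1000, 2000],
        "effect_allele": ["A", "A"], "weight": [2.0, -1.0]}))
    mean_scores = score_samples(model, data)
    np.testing.assert_allclose(mean_scores["score"], [-1.0, 0.5, 2.0])
    raw = score_samples(model, data, normalize="sum")
    np.testing.assert_allclose(raw["score"], [-2.0, 1.0, 4.0])
    assert (mean_scores["n_variants_used"] == 2).all()


def test_single_variant_identity_score():
    rng = np.random.default_rng(8)
    x = rng.binomial(2, 0.4, 50).astype(float)
    data = make_dataset(x[:, None], phenotype=np.zeros(50))
    model = GRSModel(entries=pd.DataFrame({
        "variant_id": ["v0"], "chrom": [1], "pos": [1000],
        "effect_allele": ["A"], "weight": [1.0]}))
    np.testing.assert_allclose(score_samples(model, data)["score"], x)


def test_score_allele_flip_invariance():
    rng = np.random.default_rng(9)
    X = rng.binomial(2, 0.4, (40, 2)).astype(float)
    data = make_dataset(X, phenotype=np.zeros(40))
    model = GRSModel(entries=pd.DataFrame({
        "variant_id": ["v0", "v1"], "chrom": [1, 1], "pos": [1000, 2000],
        "effect_allele": ["A", "A"], "weight": [0.5, -0.25]}))
    base = score_samples(model, data)["score"]
    flipped = make_dataset(np.column_stack([2.0 - X[:, 0], X[:, 1]]),
                           phenotype=np.zeros(40),
                           effect=["G", "A"], other=["A", "G"])
    after = score_samples(model, flipped)["score"]
    np.testing.assert_allclose(after, base, atol=1e-12)


def test_score_linearity_pre_normalization():
    rng = np.random.default_rng(10)
    X = rng.binomial(2, 0.4, (30, 3)).astype(float)
    data = make_dataset(X, phenotype=np.zeros(30))

    def model_with(w):
        return GRSModel(entries=pd.DataFrame({
            "variant_id": ["v0", "v1", "v2"], "chrom": 1,
            "pos": [1000, 2000, 3000], "effect_allele": "A", "weight": w}))

    w = np.array([0.5, -1.0, 2.0])
    v = np.array([1.5, 0.25, -0.75])
    s_w = score_samples(model_with(w), data, normalize="sum")["score"]
    s_v = score_samples(model_with(v), data, normalize="sum")["score"]
    s_wv = score_samples(model_with(w + v), data, normalize="sum")["score"]
    np.testing.assert_allclose(s_wv, s_w + s_v, atol=1e-12)


def test_score_missing_dosage_imputed_with_cohort_eaf():
    X = np.array([[0.0], [1.0], [2.0], [np.nan]])
    data = make_dataset(X, phenotype=np.zeros(4))
    model = GRSModel(entries=pd.DataFrame({
        "variant_id": ["v0"], "chrom": [1], "pos": [1000],
        "effect_allele": ["A"], "weight": [1.0]}))
    scores = score_samples(model, data)["score"]
    assert scores.iloc[3] == pytest.approx(1.0)  # 2 * eaf = 2 * 0.5


def test_score_no_variants_errors():
    rng = np.random.default_rng(11)
    data = make_dataset(rng.binomial(2, 0.3, (20, 1)).astype(float),
                        phenotype=np.zeros(20))
    model = GRSModel(entries=pd.DataFrame({
        "variant_id": ["ghost"], "chrom": [1], "pos": [1],
        "effect_allele": ["A"], "weight": [1.0]}))
    with pytest.raises(ScoreError, match="scoreable"):
        score_samples(model, data)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def test_evaluate_degenerate_score_equals_phenotype():
    rng = np.random.default_rng(12)
    n = 300
    y = rng.normal(size=n)
    cov = pd.DataFrame({"age": rng.normal(70, 5, n)})
    data = make_dataset(rng.binomial(2, 0.3, (n, 2)).astype(float), phenotype=y)
    import statsmodels.api as sm
    null_r2 = sm.OLS(y, sm.add_constant(cov)).fit().rsquared
    rep = evaluate_grs(y, data, cov)
    assert rep.incremental_r2 == pytest.approx(1.0 - null_r2, abs=1e-10)
    assert rep.ci_low <= rep.effect <= rep.ci_high


def test_evaluate_null_score_near_zero_increment():
    vals = []
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        n = 5000
        y = rng.normal(size=n)
        s = rng.normal(size=n)
        data = make_dataset(rng.binomial(2, 0.3, (n, 1)).astype(float),
                            phenotype=y)
        vals.append(evaluate_grs(s, data, None).incremental_r2)
    assert np.mean(vals) < 0.002


def test_evaluate_binary_outcome_reports_or():
    rng = np.random.default_rng(13)
    n = 500
    s = rng.normal(size=n)
    prob = 1 / (1 + np.exp(-(0.8 * s - 0.5)))
    y = (rng.random(n) < prob).astype(float)
    data = make_dataset(rng.binomial(2, 0.3, (n, 1)).astype(float),
                        phenotype=y, phenotype_type="binary")
    rep = evaluate_grs(s, data, None)
    assert rep.effect_type == "OR"
    assert rep.incremental_r2 is None
    assert rep.ci_low < rep.effect < rep.ci_high
    assert rep.effect > 1.5 and rep.p < 1e-6


def test_compare_identical_models_zero_delta(tmp_path):
    rng = np.random.default_rng(14)
    X = rng.binomial(2, 0.4, (200, 3)).astype(float)
    y = X @ [0.5, -0.2, 0.1] + rng.normal(size=200)
    data = make_dataset(X, phenotype=y)
    model = GRSModel(entries=pd.DataFrame({
        "variant_id": ["v0", "v1", "v2"], "chrom": 1, "pos": [1, 2, 3],
        "effect_allele": "A", "weight": [0.5, -0.2, 0.1]}))
    comp = compare_scores(model, model, data, None)
    assert comp.delta_incremental_r2 == pytest.approx(0.0, abs=1e-12)
    # weight-file round trip reproduces scores exactly
    path = tmp_path / "w.tsv"
    model.to_file(path)
    back = GRSModel.from_file(path)
    np.testing.assert_allclose(score_samples(back, data)["score"],
                               score_samples(model, data)["score"])


def test_better_targeted_model_wins_on_target_trait():
    """A score weighted for the target trait beats one weighted for a
    genetically correlated (r_g ~ 0.3) trait in explained variance."""
    wins = 0
    n_seeds = 10
    for seed in range(n_seeds):
        rng = np.random.default_rng(200 + seed)
        n, m = 5000, 20
        X = rng.binomial(2, 0.3, (n, m)).astype(float)
        beta_a = rng.normal(0, 1, m)
        beta_b = 0.3 * beta_a + np.sqrt(1 - 0.09) * rng.normal(0, 1, m)
        g = (X - X.mean(0)) @ beta_a
        g = g / g.std() * np.sqrt(0.25)
        y = g + rng.normal(size=n) * np.sqrt(0.75)
        data = make_dataset(X, phenotype=y)

        def model_of(w):
            return GRSModel(entries=pd.DataFrame({
                "variant_id": [f"v{j}" for j in range(m)], "chrom": 1,
                "pos": (np.arange(m) + 1) * 1000, "effect_allele": "A",
                "weight": w}))

        comp = compare_scores(model_of(beta_a), model_of(beta_b), data, None)
        wins += comp.delta_incremental_r2 > 0
    assert wins >= 9
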