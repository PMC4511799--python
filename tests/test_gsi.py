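import numpy as np
import pandas as pd
import pytest

from sscpue.errors import GSIError
from sscpue.gsi import (
    collate_monthly_composition,
    cwt_concordance,
    estimate_frequencies,
    fit_mixture_em,
    genotype_loglik,
    loglik_matrix,
    out_of_baseline_score,
    posteriors_under_pi,
    sliding_window_run,
)
from sscpue.simulate import simulate_baseline, simulate_mixture_season

from .conftest import make_genotype_table, small_config


class TestFrequencies:
    def test_posterior_mean_hand_values(self):
        # one pop, biallelic locus, genotypes (A,A) and (A,B):
        # f(A) = (3 + 1/2) / (4 + 1) = 0.7
        t = make_genotype_table(
            {"f1": {"L": ("A", "A")}, "f2": {"L": ("A", "B")}},
            meta={"f1": {"origin_label": "p1"}, "f2": {"origin_label": "p1"}},
        )
        bf = estimate_frequencies(t)
        assert bf.freqs["L"][0] == pytest.approx([0.7, 0.3])
        assert bf.gene_counts["L"][0] == 4

    def test_untyped_population_gets_uniform_prior(self):
        t = make_genotype_table(
            {"f1": {"L": ("A", "B")}, "f2": {"L": None}},
            meta={"f1": {"origin_label": "p1"}, "f2": {"origin_label": "p2"}},
        )
        bf = estimate_frequencies(t)
        assert bf.freqs["L"][1] == pytest.approx([0.5, 0.5])

    def test_frequencies_sum_to_one_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            genos, meta = {}, {}
            for i in range(rng.integers(2, 12)):
                genos[f"f{i}"] = {
                    f"L{j}": (str(rng.integers(5)), str(rng.integers(5)))
                    if rng.random() > 0.2 else None
                    for j in range(3)
                }
                meta[f"f{i}"] = {"origin_label": f"p{rng.integers(3)}"}
            t = make_genotype_table(genos, meta=meta)
            bf = estimate_frequencies(t)
            for locus in t.loci:
                assert np.allclose(bf.freqs[locus].sum(axis=1), 1.0, atol=1e-12)
                assert (bf.freqs[locus] > 0).all()

    def test_mixture_only_allele_enters_registry(self):
        base = make_genotype_table({"f1": {"L": ("A", "A")}},
                                   meta={"f1": {"origin_label": "p1"}})
        mix = make_genotype_table({"m1": {"L": ("A", "Z")}})
        bf = estimate_frequencies(base, mix)
        assert bf.registry["L"] == ["A", "Z"]
        assert (bf.freqs["L"] > 0).all()


class TestGenotypeLoglik:
    BF = {"L": np.array([0.7, 0.3])}
    REG = {"L": ["A", "B"]}

    def test_all_missing_is_zero(self):
        assert genotype_loglik({"L": None}, self.BF, self.REG) == 0.0

    def test_heterozygote(self):
        ll = genotype_loglik({"L": ("A", "B")}, self.BF, self.REG)
        assert ll == pytest.approx(np.log(2 * 0.7 * 0.3))  # log 0.42

    def test_homozygote(self):
        ll = genotype_loglik({"L": ("A", "A")}, self.BF, self.REG)
        assert ll == pytest.approx(np.log(0.49))

    def test_unknown_allele_rejected(self):
        with pytest.raises(KeyError):
            genotype_loglik({"L": ("A", "Q")}, self.BF, self.REG)

    def test_matrix_agrees_with_scalar(self):
        base = make_genotype_table(
            {"b1": {"L1": ("A", "A"), "L2": ("A", "B")},
             "b2": {"L1": ("B", "B"), "L2": ("B", "B")}},
            meta={"b1": {"origin_label": "p1"}, "b2": {"origin_label": "p2"}},
        )
        mix = make_genotype_table({"m1": {"L1": ("A", "B"), "L2": None}})
        bf = estimate_frequencies(base, mix)
        M = loglik_matrix(mix, bf)
        for j, pop in enumerate(bf.populations):
            expected = genotype_loglik(
                {"L1": ("A", "B"), "L2": None},
                {l: bf.freqs[l][j] for l in bf.loci}, bf.registry)
            assert M[0, j] == pytest.approx(expected)


def grid_search_pi(loglik, step=1e-3):
    """Exhaustive simplex grid maximisation of the mixture likelihood."""
    LL = np.asarray(loglik, float)
    n, P = LL.shape
    L = np.exp(LL - LL.max(axis=1, keepdims=True))
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    best, best_val = None, -np.inf
    if P == 2:
        cand = [(p, 1 - p) for p in ticks]
    elif P == 3:
        cand = [(a, b, 1 - a - b) for a in ticks for b in ticks if a + b <= 1 + 1e-12]
    else:
        raise NotImplementedError
    C = np.array(cand)
    vals = np.log(np.clip(L @ C.T, 1e-300, None)).sum(axis=0)
    k = int(np.argmax(vals))
    return C[k]


class TestEM:
    def test_single_population(self):
        est = fit_mixture_em(np.zeros((5, 1)))
        assert est.pi == pytest.approx([1.0])
        assert est.n_iterations == 1

    def test_symmetric_rows_stay_uniform(self):
        LL = np.tile(np.array([[-1.0, -1.0, -1.0]]), (4, 1))
        est = fit_mixture_em(LL)
        assert est.pi == pytest.approx([1 / 3] * 3)

    def test_two_fish_closed_form(self):
        # likelihood rows (0.9, 0.1), (0.2, 0.8): MLE pi_1 = 29/48
        LL = np.log(np.array([[0.9, 0.1], [0.2, 0.8]]))
        est = fit_mixture_em(LL, tol=1e-12)
        assert est.pi[0] == pytest.approx(29 / 48, abs=1e-4)
        oracle = grid_search_pi(LL)
        assert abs(est.pi[0] - oracle[0]) < 1e-3

    def test_matches_grid_search_small_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(8):
            P = rng.integers(2, 4)
            n = rng.integers(2, 7)
            LL = np.log(rng.dirichlet(np.ones(P), size=n))
            est = fit_mixture_em(LL, tol=1e-10)
            oracle = grid_search_pi(LL)
            tv = 0.5 * np.abs(est.pi - oracle).sum()
            assert tv < 2e-3

    def test_loglik_monotone_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            LL = rng.normal(-5, 2, size=(rng.integers(2, 30), rng.integers(2, 6)))
            est = fit_mixture_em(LL, max_iter=300)
            assert np.all(np.diff(est.loglik_trace) >= -1e-9)
            assert est.pi.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.allclose(est.posteriors.sum(axis=1), 1.0, atol=1e-10)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(5)
        LL = rng.normal(-3, 1, size=(20, 4))
        perm = np.array([2, 0, 3, 1])
        a = fit_mixture_em(LL, tol=1e-12)
        b = fit_mixture_em(LL[:, perm], tol=1e-12)
        assert a.pi[perm] == pytest.approx(b.pi, abs=1e-8)

    def test_group_posteriors_sum_member_populations(self):
        rng = np.random.default_rng(6)
        LL = rng.normal(-3, 1, size=(10, 4))
        GM = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], float)
        est = fit_mixture_em(LL, group_matrix=GM, group_names=["g1", "g2"])
        manual = est.posteriors @ GM
        assert np.array_equal(est.group_posteriors.to_numpy(), manual)

    def test_impossible_fish_raises(self):
        LL = np.array([[-np.inf, -np.inf], [0.0, 0.0]])
        with pytest.raises(GSIError):
            fit_mixture_em(LL)

    def test_parameter_recovery_five_populations(self):
        # 5 pops, F=0.1, 20 biallelic loci, 400 mixture fish
        true_pi = np.array([0.4, 0.3, 0.15, 0.1, 0.05])
        maes = []
        for seed in range(3):
            pi_hat, _ = _simulate_and_fit(true_pi, seed)
            maes.append(np.abs(pi_hat - true_pi).mean())
        assert np.mean(maes) < 0.05


def _simulate_and_fit(true_pi, seed, n_fish=400):
    P = len(true_pi)
    cfg = small_config(
        seed=seed, n_populations=P, n_loci=20,
        marker_type="snp", alleles_per_locus=2,
        differentiation=0.1, baseline_n_per_pop=200,
        reporting_group_map={f"P{i+1:02d}": f"G{i+1}" for i in range(P)},
        true_pi={k: np.asarray(true_pi) for k in
                 [("May", "N"), ("May", "S"), ("June", "N"), ("June", "S")]},
    )
    baseline, _, pop_freqs = simulate_baseline(cfg)
    rng = np.random.default_rng(seed + 1000)
    pops = rng.choice(P, size=n_fish, p=true_pi)
    genos = {}
    for i in range(n_fish):
        g = {}
        for locus in cfg.loci:
            p = pop_freqs[locus][pops[i]]
            a = rng.choice(2, size=2, p=p / p.sum())
            g[locus] = (f"{a[0]+1:03d}", f"{a[1]+1:03d}")
        genos[f"m{i:04d}"] = g
    mix = make_genotype_table(genos, marker_type="snp", loci=cfg.loci)
    bf = estimate_frequencies(baseline, mix)
    est = fit_mixture_em(loglik_matrix(mix, bf))
    return est.pi, pops


class TestSlidingWindow:
    def _run(self, cfg):
        baseline, _, pop_freqs = simulate_baseline(cfg)
        mixture, truth = simulate_mixture_season(cfg, pop_freqs)
        bf = estimate_frequencies(baseline, mixture)
        assignments = sliding_window_run(mixture, bf, cfg.strata)
        return assignments, mixture, truth, bf

    def test_assignments_cover_all_fish(self):
        cfg = small_config(seed=21, duplicate_rate=0.0)
        assignments, mixture, _, _ = self._run(cfg)
        assert len(assignments) == mixture.n_fish
        assert set(assignments["fish_id"]) == set(mixture.fish_ids)
        assert ((assignments["posterior"] > 0)
                & (assignments["posterior"] <= 1)).all()

    def test_single_week_season_truncates_window(self):
        cfg = small_config(seed=22, duplicate_rate=0.0)
        cfg.effort_schedule = {("May", "N", "retention"): 4}
        # restrict all fishing to a single week
        import datetime as dt
        cfg.strata.season_start = dt.date(2010, 5, 3)
        cfg.strata.season_end = dt.date(2010, 5, 9)
        baseline, _, pop_freqs = simulate_baseline(cfg)
        mixture, _ = simulate_mixture_season(cfg, pop_freqs)
        bf = estimate_frequencies(baseline, mixture)
        assignments = sliding_window_run(mixture, bf, cfg.strata)
        assert set(assignments["week"]) == {18}

    def test_focal_fit_tracks_local_shift_better_than_pooled(self):
        # true pi flips between season halves; windowed posteriors must
        # track the local mixture better than one season-pooled fit
        wins = 0
        for seed in range(10):
            cfg = small_config(
                seed=100 + seed, duplicate_rate=0.0, missing_locus_rate=0.0,
                n_populations=2, n_loci=16,
                reporting_group_map={"P01": "G1", "P02": "G2"},
                true_pi={("May", "N"): np.array([0.9, 0.1]),
                         ("May", "S"): np.array([0.9, 0.1]),
                         ("June", "N"): np.array([0.1, 0.9]),
                         ("June", "S"): np.array([0.1, 0.9])},
                catch_intensity={k: 8.0 for k in
                                 [("May", "N"), ("May", "S"),
                                  ("June", "N"), ("June", "S")]},
            )
            baseline, _, pop_freqs = simulate_baseline(cfg)
            mixture, truth = simulate_mixture_season(cfg, pop_freqs)
            bf = estimate_frequencies(baseline, mixture)
            LL = loglik_matrix(mixture, bf)
            # season-pooled posteriors
            pooled = fit_mixture_em(LL)
            Z_pooled = pooled.posteriors
            assignments = sliding_window_run(mixture, bf, cfg.strata)
            truth_idx = {f: p for f, p in
                         zip(truth.fish["fish_id"], truth.fish["pop_index"])}
            ids = mixture.fish_ids
            y = np.array([truth_idx[f] for f in ids])
            # windowed posterior prob of the true population
            win = assignments.set_index("fish_id").loc[ids]
            p_win = np.where(y == 0, win["posterior"].to_numpy(), np.nan)
            p_win_true = np.array([
                row.posterior if (row.group == f"G{y[i]+1}") else 1 - row.posterior
                for i, (_, row) in enumerate(win.iterrows())])
            p_pool_true = Z_pooled[np.arange(len(y)), y]
            if (1 - p_win_true).mean() < (1 - p_pool_true).mean():
                wins += 1
        assert wins >= 8

    def test_interior_window_pools_three_weeks(self, small_study):
        st = small_study
        bf = estimate_frequencies(st.baseline, st.mixture)
        meta = st.mixture.data
        strata = st.config.strata
        weeks = pd.Series([strata.week_of(d) for d in meta["date"]])
        areas = pd.Series([strata.area_of(la) for la in meta["lat"]])
        counts = pd.crosstab(areas, weeks)
        # bookkeeping identity on an interior week with ample neighbours
        area = counts.sum(axis=1).idxmax()
        row = counts.loc[area]
        interior = [w for w in row.index[1:-1]
                    if row.get(w - 1, 0) + row[w] + row.get(w + 1, 0) >= 5]
        assert interior, "fixture needs an interior week"
        w = interior[0]
        expected = int(row.get(w - 1, 0) + row[w] + row.get(w + 1, 0))
        mask = (areas == area) & weeks.isin([w - 1, w, w + 1])
        assert int(mask.sum()) == expected


class TestComposition:
    def test_all_one_group(self):
        a = pd.DataFrame({"month": "May", "area": "N", "group": "G",
                          "fish_id": [f"f{i}" for i in range(10)],
                          "posterior": 0.99})
        comp = collate_monthly_composition(a)
        assert comp["proportion"].tolist() == [1.0]

    def test_hand_proportions(self):
        rows = (["A"] * 6 + ["B"] * 3 + ["C"] * 1)
        a = pd.DataFrame({"month": "May", "area": "N", "group": rows,
                          "fish_id": [f"f{i}" for i in range(10)]})
        comp = collate_monthly_composition(a).set_index("group")
        assert comp.loc["A", "proportion"] == pytest.approx(0.6)
        assert comp.loc["B", "proportion"] == pytest.approx(0.3)
        assert comp.loc["C", "proportion"] == pytest.approx(0.1)

    def test_stratum_sums_to_one_random(self):
        rng = np.random.default_rng(9)
        a = pd.DataFrame({
            "month": rng.choice(["May", "June"], 200),
            "area": rng.choice(["N", "S"], 200),
            "group": rng.choice(list("ABCD"), 200),
            "fish_id": [f"f{i}" for i in range(200)],
        })
        comp = collate_monthly_composition(a)
        sums = comp.groupby(["month", "area"])["proportion"].sum()
        assert np.allclose(sums, 1.0)


class TestOutOfBaseline:
    def _bf_and_mix(self, seed, diverged_F=None):
        cfg = small_config(seed=seed, n_loci=15)
        baseline, _, pop_freqs = simulate_baseline(cfg)
        return cfg, baseline, pop_freqs

    def test_percentile_roughly_uniform_for_baseline_fish(self):
        cfg = small_config(seed=31, duplicate_rate=0.0, missing_locus_rate=0.0)
        baseline, _, pop_freqs = simulate_baseline(cfg)
        mixture, _ = simulate_mixture_season(cfg, pop_freqs)
        sub = mixture.subset(np.arange(min(200, mixture.n_fish)))
        bf = estimate_frequencies(baseline, sub)
        LL = loglik_matrix(sub, bf)
        rng = np.random.default_rng(0)
        scores = [out_of_baseline_score(sub, i, bf, int(np.argmax(LL[i])),
                                        200, rng)
                  for i in range(sub.n_fish)]
        frac_low = np.mean(np.array(scores) < 0.05)
        assert 0.01 <= frac_low <= 0.12

    def test_diverged_fish_score_low(self):
        # fish simulated from a very distinct population (F = 0.5) should
        # sit in the lower tail of their best baseline population
        cfg = small_config(seed=32, differentiation=0.5, n_loci=20,
                           duplicate_rate=0.0, missing_locus_rate=0.0)
        baseline, _, pop_freqs = simulate_baseline(cfg)
        # use only populations 1-3 as the baseline; population 4 is alien
        keep = baseline.data["origin_label"] != "P04"
        base3 = baseline.subset(keep.to_numpy())
        rng = np.random.default_rng(1)
        genos = {}
        for i in range(50):
            g = {}
            for locus in cfg.loci:
                p = pop_freqs[locus][3]
                a = rng.choice(cfg.alleles_per_locus, size=2, p=p / p.sum())
                g[locus] = (f"{a[0]+1:03d}", f"{a[1]+1:03d}")
            genos[f"alien{i}"] = g
        mix = make_genotype_table(genos, loci=cfg.loci)
        bf = estimate_frequencies(base3, mix)
        LL = loglik_matrix(mix, bf)
        scores = [out_of_baseline_score(mix, i, bf, int(np.argmax(LL[i])),
                                        300, rng)
                  for i in range(mix.n_fish)]
        assert np.median(scores) < 0.05

    def test_zero_simulations_rejected(self):
        cfg = small_config(seed=33)
        baseline, _, pop_freqs = simulate_baseline(cfg)
        mixture, _ = simulate_mixture_season(cfg, pop_freqs)
        bf = estimate_frequencies(baseline, mixture)
        with pytest.raises(ValueError):
            out_of_baseline_score(mixture, 0, bf, 0, 0, np.random.default_rng(0))


class TestCWTConcordance:
    def _assignments(self, n, n_match, posterior=0.95):
        rows = []
        for i in range(n):
            group = "G1" if i < n_match else "G2"
            rows.append({"fish_id": f"f{i}", "group": group,
                         "posterior": posterior})
        labels = {f"f{i}": "G1" for i in range(n)}
        return pd.DataFrame(rows), labels

    def test_thirty_five_of_thirty_eight(self):
        assignments, labels = self._assignments(38, 35)
        out = cwt_concordance(assignments, labels)
        assert out["compared"] == 38 and out["matching"] == 35
        assert round(100 * out["proportion"]) == 92

    def test_posterior_filter_path(self):
        assignments, labels = self._assignments(10, 10)
        assignments.loc[:4, "posterior"] = 0.5  # excluded by the 0.90 rule
        out = cwt_concordance(assignments, labels)
        assert out["compared"] == 5

    def test_all_below_threshold_undefined(self):
        assignments, labels = self._assignments(6, 6, posterior=0.5)
        out = cwt_concordance(assignments, labels)
        assert out["compared"] == 0 and np.isnan(out["proportion"])

    def test_perfect_concordance(self):
        assignments, labels = self._assignments(12, 12)
        assert cwt_concordance(assignments, labels)["proportion"] == 1.0
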