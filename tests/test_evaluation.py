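import numpy as np
import pandas as pd
import pytest

from germcore import (
    EvaluationReport,
    PhenotypeMatrix,
    Trait,
    TraitSchema,
    Thresholds,
    class_coverage,
    compare_moments,
    evaluate_core,
    kl_distance,
    mantel,
    md_vd_cr_vr,
    pca_compare,
    rank_cores,
)


def _quant_matrix(columns: dict, prefix="A"):
    schema = TraitSchema([Trait(n, "quantitative") for n in columns])
    n = len(next(iter(columns.values())))
    df = pd.DataFrame(columns, index=[f"{prefix}{i}" for i in range(n)])
    return PhenotypeMatrix(df, schema)


class TestMdVdCrVr:
    def test_core_equals_whole_identity(self, collection_300):
        idx = md_vd_cr_vr(collection_300, collection_300)
        assert idx["MD_pct"] == 0.0
        assert idx["VD_pct"] == 0.0
        assert idx["CR_pct"] == pytest.approx(100.0)
        assert idx["VR_pct"] == pytest.approx(100.0)

    def test_md_granularity(self):
        """With 8 traits and 5 shifted ones, MD% = 100*5/8 = 62.5."""
        rng = np.random.default_rng(0)
        base = {f"T{i}": rng.normal(100, 10, 400) for i in range(8)}
        whole = _quant_matrix(base)
        core_cols = {
            k: (v[:80] + (50.0 if i < 5 else 0.0))  # huge shift on 5 traits
            for i, (k, v) in enumerate(base.items())
        }
        core = _quant_matrix(core_cols)
        idx = md_vd_cr_vr(whole, core)
        assert idx["MD_pct"] == pytest.approx(62.5)
        m = len(base)
        assert (idx["VD_pct"] / (100 / m)) == pytest.approx(round(idx["VD_pct"] / (100 / m)))

    def test_vr_ratio_of_cvs(self):
        """Core dispersion inflated 1.2x around the same mean -> VR = 120."""
        rng = np.random.default_rng(1)
        cols = {f"T{i}": rng.normal(50, 5, 500) for i in range(4)}
        whole = _quant_matrix(cols)
        core_cols = {
            k: v.mean() + 1.2 * (v - v.mean()) for k, v in cols.items()
        }
        core = _quant_matrix(core_cols)
        idx = md_vd_cr_vr(whole, core)
        assert idx["VR_pct"] == pytest.approx(120.0, abs=1e-9)
        assert idx["CR_pct"] == pytest.approx(120.0, abs=1e-9)


class TestClassCoverage:
    def test_identity(self, collection_300):
        assert class_coverage(collection_300, collection_300) == pytest.approx(100.0)

    def test_enumerated_partial_coverage(self):
        schema = TraitSchema(
            [
                Trait("C1", "qualitative", classes=("a", "b", "c", "d", "e")),
                Trait("C2", "qualitative", classes=("x", "y")),
            ]
        )
        whole = PhenotypeMatrix(
            pd.DataFrame(
                {"C1": ["a", "b", "c", "d", "e", "a"], "C2": ["x", "y", "x", "y", "x", "y"]},
                index=[f"W{i}" for i in range(6)],
            ),
            schema,
        )
        core = PhenotypeMatrix(
            pd.DataFrame(
                {"C1": ["a", "b", "c", "d"], "C2": ["x", "y", "x", "y"]},
                index=[f"W{i}" for i in range(4)],
            ),
            schema,
        )
        # one trait at 4/5 = 80%, the other at 100% -> mean 90%
        assert class_coverage(whole, core) == pytest.approx(90.0)


class TestKL:
    def test_identical_samples_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 5000)
        assert kl_distance(x, x) < 1e-3

    def test_gaussian_closed_form(self):
        """KL(N(1,1) || N(0,1)) = 0.5 nats; estimator within 0.05 at n=50k."""
        rng = np.random.default_rng(1)
        w = rng.normal(0, 1, 50_000)
        c = rng.normal(1, 1, 50_000)
        assert kl_distance(w, c) == pytest.approx(0.5, abs=0.05)

    def test_nonnegative(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            w = rng.normal(0, 1, 300)
            c = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), 100)
            assert kl_distance(w, c) >= 0.0

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        w = rng.normal(0, 1, 1000)
        c = rng.normal(0.3, 1.2, 200)
        assert kl_distance(w, c) == kl_distance(w, rng.permutation(c))


class TestCompareMoments:
    def test_identity_nonsignificant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 2, 200)
        res, qq = compare_moments(x, x)
        assert res.t_p > 0.9
        assert res.levene_p > 0.9
        assert res.wilcoxon_p > 0.9
        np.testing.assert_allclose(qq["whole_quantile"], qq["core_quantile"])

    def test_one_sd_shift_detected(self):
        """t-test flags a 1-SD shift at n=500 in essentially every replicate."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            w = rng.normal(0, 1, 500)
            c = rng.normal(1, 1, 500)
            res, _ = compare_moments(w, c)
            hits += res.t_p < 0.05
        assert hits == 20

    def test_snk_two_group_consistency(self):
        # two-group SNK must agree in direction with the pooled t-test
        rng = np.random.default_rng(4)
        w = rng.normal(0, 1, 100)
        c = rng.normal(0.8, 1, 100)
        res, _ = compare_moments(w, c)
        assert res.snk_p < 0.05
        assert res.snk_q == pytest.approx(np.sqrt(2) * abs(res.t_stat), rel=0.15)

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            compare_moments([1.0, 2.0], [1.0, 2.0, 3.0])


class TestMantel:
    @staticmethod
    def _random_corr(rng, p=6):
        x = rng.normal(size=(60, p))
        return np.corrcoef(x, rowvar=False)

    def test_identical_matrices(self):
        rng = np.random.default_rng(0)
        a = self._random_corr(rng)
        r, p = mantel(a, a, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_null_behavior(self):
        rs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            r, _ = mantel(self._random_corr(rng), self._random_corr(rng), n_perm=99, seed=seed)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.1

    def test_p_bounds(self):
        rng = np.random.default_rng(1)
        r, p = mantel(self._random_corr(rng), self._random_corr(rng), n_perm=199, seed=2)
        assert 1 / 200 <= p <= 1.0

    def test_against_reference_implementation(self):
        """Cross-check r against the distance-based Mantel of scikit-bio.

        Pearson correlation is invariant to the affine map r -> 1 - r, so
        the statistic on (1-A, 1-B) pseudo-distances must match ours.
        """
        skbio_mantel = pytest.importorskip("skbio.stats.distance").mantel
        rng = np.random.default_rng(5)
        a = self._random_corr(rng)
        b = self._random_corr(rng)
        ours, _ = mantel(a, b, n_perm=99, seed=0)
        da, db = 1 - a, 1 - b
        da, db = (da + da.T) / 2, (db + db.T) / 2  # exact symmetry for skbio
        np.fill_diagonal(da, 0.0)
        np.fill_diagonal(db, 0.0)
        ref_r, _, _ = skbio_mantel(da, db, permutations=0)
        assert ours == pytest.approx(ref_r, abs=1e-10)

    def test_asymmetric_rejected(self):
        a = np.eye(3)
        b = np.eye(3)
        b[0, 1] = 0.5
        with pytest.raises(ValueError):
            mantel(a, b, n_perm=99)


class TestPCA:
    def test_duplicated_trait_closed_form(self):
        """corr [[1,1],[1,1]] has eigenvalues {2, 0}: PC1 SD = sqrt(2)."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        m = _quant_matrix({"T1": x, "T2": 2 * x + 5})
        out = pca_compare(m, m, n_components=5)
        tab = out["whole"]
        assert tab["sd"].iloc[0] == pytest.approx(np.sqrt(2), abs=1e-9)
        assert len(tab) == 1  # rank-deficient: second component omitted

    def test_independent_traits(self):
        rng = np.random.default_rng(1)
        m = _quant_matrix({f"T{i}": rng.normal(0, 1, 4000) for i in range(5)})
        tab = pca_compare(m, m)["whole"]
        np.testing.assert_allclose(tab["sd"], 1.0, atol=0.1)
        np.testing.assert_allclose(tab["proportion"], 0.2, atol=0.04)

    def test_cumulative_monotone(self, collection_300):
        core = collection_300.subset(collection_300.accession_ids[:50])
        for tab in pca_compare(collection_300, core).values():
            cum = tab["cumulative"].to_numpy()
            assert (np.diff(cum) >= -1e-12).all()
            assert cum[-1] <= 1.0 + 1e-9


class TestEvaluateAndRank:
    def test_core_equals_whole_passes_cr_vr(self, collection_300, gower_300):
        rep = evaluate_core(
            collection_300, collection_300.accession_ids, gower_300,
            mantel_permutations=99, strategy="identity",
        )
        assert rep.CR_pct == pytest.approx(100.0)
        assert rep.VR_pct == pytest.approx(100.0)
        assert rep.MD_pct == 0.0
        assert rep.class_coverage_pct == pytest.approx(100.0)
        assert rep.mantel_r == pytest.approx(1.0)
        assert rep.verdict["CR_ok"] and rep.verdict["VR_ok"]

    def test_report_json_round_trip(self, collection_300, gower_300):
        core_ids = collection_300.accession_ids[::10]
        rep = evaluate_core(
            collection_300, core_ids, gower_300, mantel_permutations=99,
            strategy="stride",
        )
        back = EvaluationReport.from_json(rep.to_json())
        assert back.strategy == rep.strategy
        assert back.VR_pct == pytest.approx(rep.VR_pct)
        assert back.distances["ENE"] == pytest.approx(rep.distances["ENE"])
        assert back.verdict == rep.verdict

    def test_rank_single_candidate(self, collection_300, gower_300):
        rep = evaluate_core(
            collection_300, collection_300.accession_ids[:30], gower_300,
            mantel_permutations=99, strategy="only",
        )
        ordered, best = rank_cores([rep])
        assert best is rep

    def _fake_report(self, strategy, ene, ane, ee, h, vd, cr=90.0, vr=110.0):
        passes = vd >= 80 and cr >= 80 and vr >= 100
        return EvaluationReport(
            strategy=strategy, n_core=10, n_whole=100,
            distances={"ENE": ene, "ANE": ane, "EE": ee},
            MD_pct=0.0, VD_pct=vd, CR_pct=cr, VR_pct=vr,
            class_coverage_pct=100.0, mean_hprime_core=h, mean_hprime_whole=h,
            hprime={}, kl={}, tests=[], mantel_r=0.9, mantel_p=0.01,
            pca={}, verdict={"MD_ok": True, "VD_ok": vd >= 80, "CR_ok": cr >= 80,
                             "VR_ok": vr >= 100, "overall": passes},
        )

    def test_dominant_core_selected(self):
        a = self._fake_report("a", ene=0.10, ane=0.10, ee=0.25, h=0.7, vd=90)
        b = self._fake_report("b", ene=0.08, ane=0.12, ee=0.20, h=0.6, vd=85)
        _, best = rank_cores([a, b])
        assert best.strategy == "a"

    def test_threshold_gate_beats_raw_distance(self):
        """A core with top E-NE but failing VD loses to a passing mid-ENE core."""
        flashy = self._fake_report("flashy", ene=0.12, ane=0.11, ee=0.28, h=0.75, vd=50)
        solid = self._fake_report("solid", ene=0.09, ane=0.12, ee=0.24, h=0.70, vd=87.5)
        ordered, best = rank_cores([flashy, solid])
        assert best.strategy == "solid"
        assert ordered[-1].strategy == "flashy"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_cores([])
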