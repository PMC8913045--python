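import itertools

import numpy as np
import pandas as pd
import pytest

from germcore import (
    ClassCoverageCoreSampler,
    DistanceOptCoreSampler,
    MaxRichnessCoreSampler,
    PhenotypeMatrix,
    Trait,
    TraitSchema,
    core_size,
    distance_summaries,
    gower_matrix,
    sample_class_coverage,
    sample_distance_opt,
    sample_max_richness,
)


def brute_force_optimum(d, k, w_ene, w_ane):
    """Exhaustive search over all subsets of size k (oracle)."""
    n = d.shape[0]
    best = -np.inf
    for combo in itertools.combinations(range(n), k):
        s = distance_summaries(d, combo)
        obj = w_ene * s.ENE - w_ane * s.ANE
        best = max(best, obj)
    return best


@pytest.fixture(scope="module")
def small_distance():
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 1, size=(12, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return d / d.max()


class TestCoreSize:
    @pytest.mark.parametrize("n,frac,expected", [(6778, 0.10, 678), (999, 0.10, 100), (10, 0.10, 1)])
    def test_round_half_up(self, n, frac, expected):
        assert core_size(n, frac) == expected

    def test_kernel_floor(self):
        assert core_size(100, 0.05, kernel_size=10) == 10

    def test_invalid(self):
        with pytest.raises(ValueError):
            core_size(100, 1.5)
        with pytest.raises(ValueError):
            core_size(3, 0.99)


class TestDistanceOpt:
    def test_matches_exhaustive_optimum(self, small_distance):
        target = brute_force_optimum(small_distance, 4, 1.0, 0.0)
        cs = sample_distance_opt(
            small_distance, list(range(12)), fraction=4 / 12 + 1e-9,
            w_ene=1.0, w_ane=0.0, seed=1, max_iter=1500,
        )
        assert cs.objective == pytest.approx(target, abs=1e-12)

    def test_matches_optimum_with_both_weights(self, small_distance):
        target = brute_force_optimum(small_distance, 4, 1.0, 1.0)
        cs = sample_distance_opt(
            small_distance, list(range(12)), fraction=4 / 12 + 1e-9,
            w_ene=1.0, w_ane=1.0, seed=2, max_iter=1500,
        )
        assert cs.objective == pytest.approx(target, abs=1e-12)

    def test_kernel_always_included(self, gower_300, collection_300):
        kernel = collection_300.accession_ids[:2]
        cs = sample_distance_opt(
            gower_300, collection_300.accession_ids, kernel=kernel, seed=0,
            max_iter=300,
        )
        assert set(kernel) <= set(cs.members)

    def test_determinism(self, small_distance):
        a = sample_distance_opt(small_distance, list(range(12)), fraction=0.34, seed=7)
        b = sample_distance_opt(small_distance, list(range(12)), fraction=0.34, seed=7)
        assert a.members == b.members
        assert a.objective == b.objective

    def test_trace_nondecreasing(self, small_distance):
        cs = sample_distance_opt(small_distance, list(range(12)), fraction=0.34, seed=3)
        assert all(b >= a for a, b in zip(cs.trace, cs.trace[1:]))

    def test_invalid_weights_and_budget(self, small_distance):
        with pytest.raises(ValueError):
            DistanceOptCoreSampler(w_ene=0, w_ane=0).fit(small_distance)
        with pytest.raises(ValueError):
            DistanceOptCoreSampler(max_iter=0).fit(small_distance)

    def test_ene_ordering_follows_weights(self, collection_300, gower_300):
        """More weight on E-NE yields more diverse (higher-ENE) cores."""
        ids = collection_300.accession_ids
        ene_heavy, ane_heavy = [], []
        for seed in range(3):
            a = sample_distance_opt(gower_300, ids, w_ene=1.0, w_ane=0.0, seed=seed, max_iter=800)
            b = sample_distance_opt(gower_300, ids, w_ene=0.0, w_ane=1.0, seed=seed, max_iter=800)
            pos = {x: i for i, x in enumerate(ids)}
            ene_heavy.append(distance_summaries(gower_300, [pos[m] for m in a.members]).ENE)
            ane_heavy.append(distance_summaries(gower_300, [pos[m] for m in b.members]).ENE)
        assert np.mean(ene_heavy) > np.mean(ane_heavy)


@pytest.fixture
def rare_class_matrix():
    schema = TraitSchema(
        [
            Trait("Q", "quantitative", bin_rule="fixed:2"),
            Trait("C", "qualitative", classes=("common", "rare")),
        ]
    )
    df = pd.DataFrame(
        {
            "Q": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0],
            "C": ["common"] * 9 + ["rare"],
        },
        index=[f"A{i}" for i in range(10)],
    )
    return PhenotypeMatrix(df, schema)


class TestMaxRichness:
    def test_rare_class_carrier_always_selected(self, rare_class_matrix):
        # necessity: only A9 carries class "rare"
        for seed in range(5):
            cs = sample_max_richness(rare_class_matrix, fraction=0.3, seed=seed)
            assert "A9" in cs.members

    def test_removing_members_never_increases_richness(self, rare_class_matrix):
        from germcore.core_samplers import _class_table, _richness

        cs = sample_max_richness(rare_class_matrix, fraction=0.4, seed=0)
        table = _class_table(rare_class_matrix)
        ids = rare_class_matrix.accession_ids
        idx = [ids.index(m) for m in cs.members]
        full = _richness(table, idx)
        for drop in range(len(idx)):
            sub = idx[:drop] + idx[drop + 1 :]
            assert _richness(table, sub) <= full

    def test_determinism_and_kernel(self, rare_class_matrix):
        a = sample_max_richness(rare_class_matrix, fraction=0.3, kernel=["A0"], seed=1)
        b = sample_max_richness(rare_class_matrix, fraction=0.3, kernel=["A0"], seed=1)
        assert a.members == b.members
        assert "A0" in a.members


class TestClassCoverage:
    def test_minimal_cover_found(self):
        # 2 accessions jointly carry all classes; cover must have <= 2 extras
        schema = TraitSchema(
            [
                Trait("C1", "qualitative", classes=("a", "b")),
                Trait("C2", "qualitative", classes=("x", "y")),
            ]
        )
        df = pd.DataFrame(
            {"C1": ["a", "b", "a", "a"], "C2": ["x", "y", "x", "x"]},
            index=["A0", "A1", "A2", "A3"],
        )
        m = PhenotypeMatrix(df, schema)
        est = ClassCoverageCoreSampler(fraction=0.5, random_state=0).fit(m)
        # set-cover enumeration: {A0, A1} covers everything
        covered = set()
        for mem in est.members_:
            covered |= {(c, df.loc[mem, c]) for c in df.columns}
        assert covered == {("C1", "a"), ("C1", "b"), ("C2", "x"), ("C2", "y")}

    def test_full_class_coverage_postcondition(self, collection_300):
        cs = sample_class_coverage(collection_300, fraction=0.15, seed=0)
        core = collection_300.subset(cs.members)
        for t in collection_300.schema.qualitative:
            whole_classes = set(collection_300.values[t].dropna().unique())
            assert set(core.values[t].dropna().unique()) == whole_classes

    def test_determinism(self, collection_300):
        a = sample_class_coverage(collection_300, seed=4)
        b = sample_class_coverage(collection_300, seed=4)
        assert a.members == b.members

    def test_size_violation_flagged(self):
        # many classes spread so the cover exceeds the tiny target size
        rng = np.random.default_rng(0)
        schema = TraitSchema(
            [Trait("C", "qualitative", classes=tuple(f"c{i}" for i in range(10)))]
        )
        df = pd.DataFrame(
            {"C": [f"c{i}" for i in range(10)] * 2},
            index=[f"A{i}" for i in range(20)],
        )
        m = PhenotypeMatrix(df, schema)
        cs = sample_class_coverage(m, fraction=0.1, seed=0)  # target 2 < cover 10
        assert cs.size_violation
        assert len(cs.members) == 10


class TestBatteryInvariants:
    def test_all_samplers_exact_size_and_kernel(self, collection_300, gower_300):
        ids = collection_300.accession_ids
        kernel = ids[:3]
        target = core_size(300, 0.10, kernel_size=3)
        for cs in (
            sample_distance_opt(gower_300, ids, kernel=kernel, seed=0, max_iter=200),
            sample_max_richness(collection_300, kernel=kernel, seed=0),
            sample_class_coverage(collection_300, kernel=kernel, seed=0, d=gower_300),
        ):
            assert len(cs.members) == target
            assert set(kernel) <= set(cs.members)
            assert len(set(cs.members)) == len(cs.members)
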