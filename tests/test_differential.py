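import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from splicescape import differential as diff
from splicescape.synthetic import SimulationConfig, simulate

from oracles import oracle_bh, oracle_hypergeom_tail


def _matrix(values: dict, conditions: dict, gene_map=None):
    df = pd.DataFrame(values)
    gene_map = gene_map or {t: t for t in df.index}
    return diff.ExpressionMatrix(df, conditions, gene_map)


def _simple(noise=0.0, seed=0, n=50, de=(), lfc=2.0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n)]
    base = rng.lognormal(4, 1, size=n)
    cols = {}
    for cond in ("A", "B"):
        for rep in (1, 2):
            shift = np.where(np.isin(genes, list(de)) & (cond == "B"),
                             2.0 ** lfc, 1.0)
            eps = np.exp(noise * rng.standard_normal(n))
            cols[f"{cond}_{rep}"] = base * shift * eps
    df = pd.DataFrame(cols, index=genes)
    return diff.ExpressionMatrix(
        df, {c: c.split("_")[0] for c in df.columns}, {g: g for g in genes})


class TestCallDe:
    def test_identical_conditions_nothing_called(self):
        m = _simple(noise=0.0)
        res = diff.call_de(m, ("A", "B"))
        assert all(r.log2_fold_change == 0 for r in res)
        assert not any(r.is_de for r in res)

    def test_planted_fourfold_noiseless_exactly_recovered(self):
        de = {"g1", "g5", "g7"}
        m = _simple(noise=0.0, de=de, lfc=2.0)
        res = diff.call_de(m, ("B", "A"))
        called = {r.gene_id for r in res if r.is_de}
        assert called == de

    def test_simulation_fdr_and_power(self):
        """200 genes, 10% DE at |log2FC|=2, 2 replicates: empirical FDR
        among calls <= 0.05 and power >= 0.8."""
        b = simulate(SimulationConfig(seed=7, n_genes=200))
        res = diff.call_de(b.expression, ("NA", "CS"))
        truth = {g.gene_id for g in b.truth.genes if g.de_log2fc}
        called = {r.gene_id for r in res if r.is_de}
        fdr = len(called - truth) / max(1, len(called))
        power = len(called & truth) / max(1, len(truth))
        assert fdr <= 0.05
        assert power >= 0.8

    def test_pure_null_type_one_error(self):
        """Under a pure null, the DE decision rule fires on <= 2% of genes."""
        b = simulate(SimulationConfig(seed=7, n_genes=200, de_fraction=0.0))
        res = diff.call_de(b.expression, ("NA", "CS"))
        type1 = sum(r.is_de for r in res) / len(res)
        assert type1 <= 0.02

    def test_contrast_symmetry(self):
        m = _simple(noise=0.2, de={"g3"}, seed=4)
        ab = diff.call_de(m, ("A", "B"))
        ba = diff.call_de(m, ("B", "A"))
        for r1, r2 in zip(ab, ba):
            assert r1.gene_id == r2.gene_id
            assert r1.log2_fold_change == pytest.approx(-r2.log2_fold_change)
            assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)

    def test_monotonicity_in_alpha_and_min_fc(self):
        m = _simple(noise=0.3, de={"g1", "g2", "g3", "g4"}, seed=9)
        rng = np.random.default_rng(1)
        for _ in range(20):
            a1, a2 = sorted(rng.uniform(1e-4, 0.2, size=2))
            f1, f2 = sorted(rng.uniform(1.1, 4.0, size=2))
            n_loose = sum(r.is_de for r in diff.call_de(
                m, ("A", "B"), alpha=a2, min_fc=f1))
            n_tight_alpha = sum(r.is_de for r in diff.call_de(
                m, ("A", "B"), alpha=a1, min_fc=f1))
            n_tight_fc = sum(r.is_de for r in diff.call_de(
                m, ("A", "B"), alpha=a2, min_fc=f2))
            assert n_tight_alpha <= n_loose
            assert n_tight_fc <= n_loose

    def test_zero_signal_condition_error(self):
        df = pd.DataFrame({"A_1": [0.0, 0.0], "B_1": [1.0, 2.0]},
                          index=["g1", "g2"])
        m = diff.ExpressionMatrix(df, {"A_1": "A", "B_1": "B"},
                                  {"g1": "g1", "g2": "g2"})
        with pytest.raises(diff.ExpressionError):
            diff.call_de(m, ("A", "B"))

    def test_gene_level_aggregation_sums_transcripts(self):
        df = pd.DataFrame({"A_1": [10.0, 20.0, 5.0], "B_1": [1.0, 2.0, 5.0]},
                          index=["t1.1", "t1.2", "t2.1"])
        m = diff.ExpressionMatrix(df, {"A_1": "A", "B_1": "B"},
                                  {"t1.1": "g1", "t1.2": "g1", "t2.1": "g2"})
        gv = m.gene_values()
        assert gv.loc["g1", "A_1"] == 30.0
        assert gv.loc["g2", "B_1"] == 5.0

    def test_welch_alternative_detects_shift_with_replicates(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(40)]
        base = rng.lognormal(4, 0.5, size=40)
        cols = {}
        for cond in ("A", "B"):
            for rep in range(1, 6):
                shift = np.where([g == "g1" for g in genes],
                                 8.0 if cond == "B" else 1.0, 1.0)
                eps = np.exp(0.05 * rng.standard_normal(40))
                cols[f"{cond}_{rep}"] = base * shift * eps
        df = pd.DataFrame(cols, index=genes)
        m = diff.ExpressionMatrix(
            df, {c: c.split("_")[0] for c in df.columns},
            {g: g for g in genes})
        res = diff.call_de(m, ("A", "B"), method="welch", alpha=0.05)
        assert {r.gene_id for r in res if r.is_de} == {"g1"}


class TestBenjaminiHochberg:
    def test_matches_bruteforce_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        p = rng.uniform(size=10_000)
        q = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, oracle_bh(list(p)))

    def test_q_monotone_in_p_rank(self):
        m = _simple(noise=0.3, de={"g1"}, seed=2)
        res = diff.call_de(m, ("A", "B"))
        ordered = sorted(res, key=lambda r: r.p_value)
        qs = [r.q_value for r in ordered]
        assert qs == sorted(qs)


class TestCallDags:
    def test_de_without_as_is_not_dag(self):
        r = diff.DagResult("g1", ("A", "B"), 1, 1, 2.0, 5.0, 1e-6, 1e-5,
                           is_de=True)
        out = diff.call_dags([r], {"A": set(), "B": set()})
        assert not out[0].is_dag

    def test_as_without_de_is_not_dag(self):
        r = diff.DagResult("g1", ("A", "B"), 1, 1, 0.0, 0.0, 0.9, 0.95,
                           is_de=False)
        out = diff.call_dags([r], {"A": {"g1"}, "B": set()})
        assert out[0].has_as and not out[0].is_dag

    def test_planted_intersection_recovered_exactly(self):
        """DAGs equal the planted DE-and-AS gene set."""
        b = simulate(SimulationConfig(seed=7, n_genes=200))
        res = diff.call_de(b.expression, ("NA", "CS"))
        as_sets = b.truth.as_gene_sets()
        res = diff.call_dags(res, as_sets)
        truth_de = {g.gene_id for g in b.truth.genes if g.de_log2fc}
        truth_dag = truth_de & (as_sets["NA"] | as_sets["CS"])
        assert {r.gene_id for r in res if r.is_dag} == truth_dag

    def test_overlap_summary_counts(self):
        def mk(gid, de, as_):
            return diff.DagResult(gid, ("A", "B"), 1, 1, 2, 5, 1e-6, 1e-5,
                                  is_de=de, has_as=as_, is_dag=de and as_)
        by_contrast = {
            "A:B": [mk("g1", True, True), mk("g2", True, True)],
            "A:C": [mk("g1", True, True), mk("g3", True, True)],
        }
        s = diff.dag_overlap(by_contrast)
        assert s["counts"] == {"A:B": 2, "A:C": 2}
        assert s["pairwise_overlap"] == {"A:B&A:C": 1}
        assert s["unique"] == {"A:B": 1, "A:C": 1}
        assert s["common"] == 1


class TestEnrich:
    def test_closed_form_contingency(self):
        """k=5, K=10, n=50, N=100 equals the exact hypergeometric tail."""
        universe = {f"g{i}" for i in range(100)}
        term_map = {f"g{i}": ["T"] for i in range(10)}
        study = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(10, 55)}
        table = diff.enrich(study, universe, term_map)
        row = table[table["term"] == "T"].iloc[0]
        assert (row["k"], row["K"], row["n"], row["N"]) == (5, 10, 50, 100)
        assert row["p"] == pytest.approx(
            oracle_hypergeom_tail(5, 100, 10, 50), rel=1e-12)

    def test_extreme_enrichment_minimal_p(self):
        universe = {f"g{i}" for i in range(50)}
        term_map = {f"g{i}": ["A"] for i in range(5)}
        term_map.update({f"g{i}": ["B"] for i in range(5, 30)})
        study = {f"g{i}" for i in range(5)}
        table = diff.enrich(study, universe, term_map)
        assert table.iloc[0]["term"] == "A"

    def test_null_pvalues_approximately_uniform(self):
        """Hypergeometric p-values under random draws pass a KS test."""
        rng = np.random.default_rng(5)
        big_n, n_study = 20_000, 4_000
        universe = np.arange(big_n)
        universe_set = {f"g{i}" for i in universe}
        pvals = []
        for _ in range(500):
            big_k = int(rng.integers(1_000, 4_000))
            perm = rng.permutation(universe)
            members = perm[:big_k]
            study = {f"g{i}" for i in rng.permutation(universe)[:n_study]}
            term_map = {f"g{i}": ["T"] for i in members}
            table = diff.enrich(study, universe_set, term_map)
            pvals.append(table.iloc[0]["p"])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_empty_term_map_error(self):
        with pytest.raises(ValueError):
            diff.enrich({"g1"}, {"g1"}, {})

    def test_study_outside_universe_error(self):
        with pytest.raises(ValueError):
            diff.enrich({"gX"}, {"g1"}, {"g1": ["T"]})
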