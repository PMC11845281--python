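"""Statistical core: contingency counts, hypergeometric tail, BH, results."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact, hypergeom

from koenrich.annotation_io import AnnotationMap
from koenrich.enrichment import (
    ContingencyCounts,
    EnrichmentTable,
    bh_adjust,
    filter_significant,
    fold_enrichment,
    hypergeom_pvalue,
    make_query,
    read_results,
    run_enrichment,
    write_results,
)
from koenrich.pathway_map import PathwayCatalog, build_term2gene
from koenrich.synthetic import SpikeDesign, generate_dataset


def exact_upper_tail(k: int, n: int, K: int, N: int) -> Fraction:
    """Independent oracle: exact rational pmf sum over the upper tail."""
    total = math.comb(N, n)
    return Fraction(
        sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(n, K) + 1)),
        total,
    )


class TestContingencyCounts:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(k=6, n=5, K=10, N=20),   # k > n
            dict(k=0, n=5, K=19, N=20),   # k < n + K - N
            dict(k=1, n=25, K=5, N=20),   # n > N
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ContingencyCounts(**kwargs)


class TestHypergeomPvalue:
    def test_k_zero_is_one(self):
        assert hypergeom_pvalue(ContingencyCounts(k=0, n=5, K=5, N=20)) == 1.0

    def test_all_draws_in_pathway(self):
        # P(X = 5) with N=10, K=5, n=5 is 1 / C(10,5) = 1/252
        p = hypergeom_pvalue(ContingencyCounts(k=5, n=5, K=5, N=10))
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_hand_summed_tail(self):
        # C(3,2)C(3,1) + C(3,3)C(3,0) over C(6,3) = 10/20
        p = hypergeom_pvalue(ContingencyCounts(k=2, n=3, K=3, N=6))
        assert p == pytest.approx(0.5, rel=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.data())
    def test_matches_exact_enumeration(self, data):
        N = data.draw(st.integers(2, 25))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(max(0, n + K - N), min(n, K)))
        p = hypergeom_pvalue(ContingencyCounts(k=k, n=n, K=K, N=N))
        assert p == pytest.approx(float(exact_upper_tail(k, n, K, N)), rel=1e-12)

    def test_matches_scipy_sf_at_scale(self):
        # survival-function cross-check at a realistic universe size
        c = ContingencyCounts(k=40, n=400, K=300, N=12000)
        assert hypergeom_pvalue(c) == pytest.approx(
            float(hypergeom.sf(39, 12000, 300, 400)), rel=1e-10
        )

    def test_strictly_decreasing_in_k(self):
        N, K, n = 60, 20, 15
        ps = [
            hypergeom_pvalue(ContingencyCounts(k=k, n=n, K=K, N=N))
            for k in range(0, min(n, K) + 1)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_fisher_one_sided_equivalence_small_grid(self):
        for N in (8, 12, 17):
            for K in range(1, N):
                for n in range(1, N):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        table = [[k, n - k], [K - k, N - K - n + k]]
                        pf = fisher_exact(table, alternative="greater")[1]
                        ph = hypergeom_pvalue(ContingencyCounts(k=k, n=n, K=K, N=N))
                        assert ph == pytest.approx(pf, abs=1e-10)


class TestFoldEnrichment:
    def test_arithmetic(self):
        assert fold_enrichment(ContingencyCounts(k=4, n=10, K=8, N=100)) == 5.0

    def test_equal_fractions_give_one(self):
        assert fold_enrichment(ContingencyCounts(k=2, n=10, K=4, N=20)) == 1.0

    def test_zero_k(self):
        assert fold_enrichment(ContingencyCounts(k=0, n=10, K=4, N=20)) == 0.0

    def test_undefined_for_zero_denominators(self):
        with pytest.raises(ValueError):
            fold_enrichment(ContingencyCounts(k=0, n=0, K=4, N=20))
        with pytest.raises(ValueError):
            fold_enrichment(ContingencyCounts(k=0, n=10, K=0, N=20))

    @settings(derandomize=True, max_examples=100)
    @given(st.data())
    def test_above_one_iff_overrepresented(self, data):
        N = data.draw(st.integers(4, 40))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(max(0, n + K - N), min(n, K)))
        fe = fold_enrichment(ContingencyCounts(k=k, n=n, K=K, N=N))
        assert (fe > 1) == (k / n > K / N)


def bh_oracle(pvals: list[float]) -> list[float]:
    """Direct step-up formula: adj_(i) = min(1, min_{j>=i} p_(j) * m / j)."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, pvals[order[rank - 1]] * m / rank)
        adj_sorted[rank - 1] = min(1.0, running)
    out = np.empty(m)
    out[order] = adj_sorted
    return out.tolist()


class TestBHAdjust:
    def test_handworked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_value_identity(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_step_up_carries_minimum_down(self):
        assert bh_adjust([0.5, 0.9]) == pytest.approx([0.9, 0.9])

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [-0.1], []])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.floats(1e-12, 1.0, exclude_min=False, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_matches_formula_oracle_and_bounds(self, pvals):
        adj = bh_adjust(pvals)
        assert adj == pytest.approx(bh_oracle(pvals), rel=1e-12, abs=1e-15)
        for raw, a in zip(pvals, adj):
            assert raw <= a + 1e-15
            assert a <= 1.0

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=2, max_size=20),
        st.randoms(use_true_random=False),
    )
    def test_permutation_equivariant(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        adj = bh_adjust(pvals)
        adj_perm = bh_adjust([pvals[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm], rel=1e-12)


def build_universe(n_universe: int, pathway_members: dict[str, list[int]]):
    """Build an annotation/catalog pair realizing given pathway memberships."""
    cat = PathwayCatalog()
    entries: dict[str, set[str]] = {f"g{i}": set() for i in range(n_universe)}
    for j, (pid, members) in enumerate(sorted(pathway_members.items())):
        ko = f"K{j + 1:05d}"
        cat.add(pid, f"Pathway {pid}", {ko})
        for i in members:
            entries[f"g{i}"].add(ko)
    # a filler pathway so every gene is annotated (universe == background)
    filler = f"K{len(pathway_members) + 1:05d}"
    cat.add("ko09990", "Filler", {filler})
    for kos in entries.values():
        kos.add(filler)
    amap = AnnotationMap(entries=entries)
    return amap, cat, build_term2gene(amap, cat)


class TestMakeQuery:
    def test_universe_and_effective_foreground(self):
        _, _, t2g = build_universe(2, {"ko00010": [0, 1]})
        q = make_query(["g0"], ["g0", "g1"], t2g)
        assert q.universe == {"g0", "g1"}
        assert q.effective_foreground == {"g0"}

    def test_foreground_outside_background_dropped_with_warning(self, caplog):
        _, _, t2g = build_universe(2, {"ko00010": [0, 1]})
        with caplog.at_level("WARNING", logger="koenrich"):
            q = make_query(["g0", "gX"], ["g0", "g1"], t2g)
        assert q.n_fg_not_in_background == 1
        assert "dropped" in caplog.text

    def test_unannotated_background_excluded_from_universe(self):
        cat = PathwayCatalog()
        cat.add("ko00010", "P", {"K00001"})
        amap = AnnotationMap(entries={"g0": {"K00001"}, "g2": {"K99999"}})
        t2g = build_term2gene(amap, cat)
        q = make_query(["g0"], ["g0", "g1", "g2"], t2g)
        assert q.universe == {"g0"}
        assert q.n_bg_unannotated == 2

    def test_no_annotated_foreground_is_hard_error(self):
        _, _, t2g = build_universe(3, {"ko00010": [0]})
        with pytest.raises(ValueError, match="no annotated foreground"):
            make_query(["gX"], ["g0", "g1", "g2"], t2g)


class TestRunEnrichment:
    def test_foreground_equals_background_identity(self):
        _, cat, t2g = build_universe(
            10, {"ko00010": [0, 1, 2], "ko00020": [3, 4]}
        )
        genes = [f"g{i}" for i in range(10)]
        table = run_enrichment(make_query(genes, genes, t2g), t2g, cat)
        for r in table:
            assert r.p_value == pytest.approx(1.0)
            assert r.fold_enrichment == pytest.approx(1.0)

    def test_single_pathway_matches_enumeration_oracle(self):
        # universe of 20, one real pathway with K=5; fg of 6 with k=4
        _, cat, t2g = build_universe(20, {"ko00010": [0, 1, 2, 3, 4]})
        fg = ["g0", "g1", "g2", "g3", "g10", "g11"]
        bg = [f"g{i}" for i in range(20)]
        table = run_enrichment(make_query(fg, bg, t2g), t2g, cat)
        rec = next(r for r in table if r.pathway_id == "ko00010")
        expected = float(exact_upper_tail(4, 6, 5, 20))
        assert rec.p_value == pytest.approx(expected, rel=1e-12)
        assert rec.k == 4 and rec.K == 5 and rec.n == 6 and rec.N == 20

    def test_spiked_fixture_ranks_first(self):
        design = SpikeDesign(
            n_genes=2000,
            n_pathways=50,
            kos_per_pathway=(10, 30),
            kos_per_gene=(1, 3),
            fg_size=200,
            spiked_pathway_count=1,
            spike_fraction=0.5,
            seed=1,
        )
        ds = generate_dataset(design)
        q = make_query(ds.foreground, ds.background, ds.t2g)
        table = run_enrichment(q, ds.t2g, ds.catalog)
        assert table.records[0].pathway_id == ds.truth[0]["pathway_id"]

    def test_invariant_to_input_order_and_duplicates(self):
        _, cat, t2g = build_universe(10, {"ko00010": [0, 1, 2]})
        bg = [f"g{i}" for i in range(10)]
        fg = ["g0", "g1", "g5"]
        t1 = run_enrichment(make_query(fg, bg, t2g), t2g, cat)
        t2 = run_enrichment(make_query(fg[::-1] + ["g0"], bg[::-1] + bg, t2g), t2g, cat)
        assert [(r.pathway_id, r.p_value) for r in t1] == [
            (r.pathway_id, r.p_value) for r in t2
        ]

    def test_drop_empty_restricts_bh_family(self):
        _, cat, t2g = build_universe(
            12, {"ko00010": [0, 1, 2], "ko00020": [6, 7, 8]}
        )
        bg = [f"g{i}" for i in range(12)]
        fg = ["g0", "g1", "g2"]
        full = run_enrichment(make_query(fg, bg, t2g), t2g, cat)
        dropped = run_enrichment(make_query(fg, bg, t2g), t2g, cat, drop_empty=True)
        assert len(dropped) < len(full)
        assert all(r.k >= 1 for r in dropped)

    def test_sorted_by_padj_then_p_then_id(self, small_table):
        keys = [(r.p_adjusted, r.p_value, r.pathway_id) for r in small_table]
        assert keys == sorted(keys)


class TestFilterSignificant:
    def make_table(self, padjs):
        _, cat, t2g = build_universe(10, {"ko00010": [0, 1, 2]})
        # real records not needed; fabricate minimal table via run + patching p
        table = run_enrichment(
            make_query(["g0", "g1"], [f"g{i}" for i in range(10)], t2g), t2g, cat
        )
        return table

    def test_strict_threshold(self, small_table):
        from dataclasses import replace

        recs = [replace(small_table.records[0], p_adjusted=0.045, p_value=0.01)]
        table = EnrichmentTable(records=recs)
        assert len(filter_significant(table, by="padj", alpha=0.05)) == 1
        recs = [replace(small_table.records[0], p_adjusted=0.05, p_value=0.01)]
        assert len(filter_significant(EnrichmentTable(records=recs), "padj", 0.05)) == 0

    def test_alpha_one_retains_everything(self, small_table):
        assert len(filter_significant(small_table, "padj", 1.0)) == len(small_table)

    @pytest.mark.parametrize("alpha", [0.0, 1.5, -1])
    def test_alpha_out_of_range(self, small_table, alpha):
        with pytest.raises(ValueError):
            filter_significant(small_table, "padj", alpha)


class TestResultsIO:
    def test_ratio_formatting(self, tmp_path):
        from dataclasses import replace

        _, cat, t2g = build_universe(20, {"ko00010": [0, 1, 2, 3, 4]})
        table = run_enrichment(
            make_query(["g0", "g1", "g5", "g6"], [f"g{i}" for i in range(20)], t2g),
            t2g,
            cat,
        )
        path = tmp_path / "results.tsv"
        write_results(table, path)
        text = path.read_text()
        assert "2/4" in text and "5/20" in text

    def test_empty_table_header_only(self, tmp_path):
        path = tmp_path / "results.tsv"
        assert write_results(EnrichmentTable(), path) == 0
        assert len(path.read_text().splitlines()) == 1

    def test_roundtrip_to_printed_precision(self, tmp_path, small_table):
        path = tmp_path / "results.tsv"
        rows = write_results(small_table, path)
        back = read_results(path)
        assert rows == len(small_table)
        for a, b in zip(small_table, back):
            assert a.pathway_id == b.pathway_id
            assert a.genes == b.genes
            assert b.p_value == pytest.approx(a.p_value, rel=1e-8)
            assert b.fold_enrichment == pytest.approx(a.fold_enrichment, rel=1e-8)
            assert (a.k, a.n, a.K, a.N) == (b.k, b.n, b.K, b.N)
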