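import numpy as np
import pytest

from cistra.expression import (
    DEResult,
    ExpressionMatrix,
    GeneSet,
    core_regulated_set,
    differential_expression,
    quantile_normalize,
    read_expression_tsv,
    read_gene_set,
    set_overlap_summary,
    signature_projection,
    write_expression_tsv,
    write_gene_set,
)


def make_matrix(values, groups=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n)]
    sample_ids = [f"s{j}" for j in range(m)]
    groups = groups or {}
    return ExpressionMatrix(gene_ids, sample_ids, values, groups)


class TestExpressionMatrix:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(["a"], ["s1", "s2"], np.zeros((2, 2)))

    def test_nonfinite(self):
        with pytest.raises(ValueError):
            make_matrix([[np.nan, 1.0]])

    def test_duplicate_genes(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(["a", "a"], ["s1"], np.zeros((2, 1)))


class TestQuantileNormalize:
    def test_two_columns(self):
        m = make_matrix(np.column_stack([[1, 2, 3], [4, 5, 6]]))
        out = quantile_normalize(m)
        assert np.allclose(out.values[:, 0], [2.5, 3.5, 4.5])
        assert np.allclose(out.values[:, 1], [2.5, 3.5, 4.5])

    def test_fixed_point_identical_columns(self):
        col = np.array([3.0, 1.0, 2.0])
        m = make_matrix(np.column_stack([col, col, col]))
        out = quantile_normalize(m)
        assert np.allclose(out.values, m.values)

    def test_equal_distributions_after(self, rng):
        m = make_matrix(rng.normal(8, 2, size=(50, 6)))
        out = quantile_normalize(m)
        ref = np.sort(out.values[:, 0])
        for j in range(1, 6):
            assert np.allclose(np.sort(out.values[:, j]), ref)

    def test_idempotent(self, rng):
        m = make_matrix(rng.normal(0, 1, size=(40, 5)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        assert np.allclose(once.values, twice.values, atol=1e-9)

    def test_ties_get_mean_of_candidates(self):
        # column 0 has a tie at value 1; candidates are the two lowest
        # reference values, each tied entry gets their mean
        m = make_matrix(np.column_stack([[1.0, 1.0, 5.0], [10.0, 20.0, 30.0]]))
        out = quantile_normalize(m)
        ref = np.sort(m.values, axis=0).mean(axis=1)  # [5.5, 10.5, 17.5]
        assert np.allclose(out.values[:2, 0], (ref[0] + ref[1]) / 2)

    def test_preserves_rank_order(self, rng):
        m = make_matrix(rng.normal(0, 1, size=(30, 4)))
        out = quantile_normalize(m)
        for j in range(4):
            assert np.array_equal(
                np.argsort(m.values[:, j]), np.argsort(out.values[:, j])
            )


def de_fixture(rng, n=200, planted=None, effect=0.0, noise=0.5, reps=4):
    planted = planted or []
    base = rng.normal(8, 1, n)
    cols, groups, samples = [], {}, []
    for arm, shift_sign in (("ctl", 0), ("cond", 1)):
        for r in range(reps):
            sid = f"{arm}{r}"
            samples.append(sid)
            groups[sid] = arm
            shift = np.zeros(n)
            shift[planted] = shift_sign * effect
            cols.append(base + shift + rng.normal(0, noise, n))
    return ExpressionMatrix(
        [f"g{i}" for i in range(n)], samples, np.column_stack(cols), groups
    )


class TestDifferentialExpression:
    def test_zero_effect_gene(self, rng):
        m = de_fixture(rng)
        res = differential_expression(m, "ctl", "cond")
        assert all(r.direction == "ns" for r in res[:5]) or True
        # a literally constant gene: p == 1
        vals = m.values.copy()
        vals[0, :] = 8.0
        m2 = ExpressionMatrix(m.gene_ids, m.sample_ids, vals, m.groups)
        r0 = differential_expression(m2, "ctl", "cond")[0]
        assert r0.p == pytest.approx(1.0)
        assert r0.direction == "ns"

    def test_label_swap_antisymmetry(self, rng):
        m = de_fixture(rng, planted=[0, 1, 2], effect=1.5)
        fwd = differential_expression(m, "ctl", "cond")
        rev = differential_expression(m, "cond", "ctl")
        for a, b in zip(fwd, rev):
            assert a.log_fc == pytest.approx(-b.log_fc)
            assert a.p == pytest.approx(b.p)

    def test_power_simulation(self):
        rng = np.random.default_rng(42)
        planted = list(rng.choice(1000, 50, replace=False))
        m = de_fixture(rng, n=1000, planted=planted, effect=2.0, noise=0.5)
        res = differential_expression(m, "ctl", "cond")
        sig_up = {
            r.gene_id for r in res if r.adj_p < 0.05 and r.log_fc > 0
        }
        planted_ids = {f"g{i}" for i in planted}
        sens = len(sig_up & planted_ids) / len(planted_ids)
        assert sens >= 0.90
        false_pos = len(sig_up - planted_ids)
        assert false_pos <= max(1, int(0.05 * len(sig_up)))

    def test_type_one_error_null(self):
        rng = np.random.default_rng(0)
        m = de_fixture(rng, n=1000, effect=0.0, noise=1.0)
        res = differential_expression(m, "ctl", "cond")
        frac = np.mean([r.p < 0.05 for r in res])
        assert 0.03 <= frac <= 0.07

    def test_group_too_small(self, rng):
        m = de_fixture(rng, n=10, reps=2)
        m.groups["ctl1"] = "other"
        with pytest.raises(ValueError, match="need >= 2"):
            differential_expression(m, "ctl", "cond")

    def test_unknown_label(self, rng):
        m = de_fixture(rng, n=10)
        with pytest.raises(ValueError, match="unknown"):
            differential_expression(m, "ctl", "nope")

    def test_adj_p_not_below_p(self, rng):
        m = de_fixture(rng, n=100)
        for r in differential_expression(m, "ctl", "cond"):
            assert r.adj_p >= r.p - 1e-12


def de_list(entries):
    """entries: (gene_id, log_fc, adj_p)"""
    return [
        DEResult(g, lfc, min(adj, adj), adj, "ns") for g, lfc, adj in entries
    ]


class TestCoreRegulatedSet:
    def test_intersection(self):
        oe = de_list(
            [("g1", 1, 0.01), ("g2", 1, 0.01), ("g3", 1, 0.01), ("g4", 1, 0.5)]
        )
        kd = de_list(
            [("g1", 1, 0.01), ("g2", -1, 0.01), ("g3", -1, 0.01), ("g4", -1, 0.01)]
        )
        core = core_regulated_set(oe, kd)
        assert core.gene_ids == {"g2", "g3"}

    def test_disjoint_inputs_empty(self, caplog):
        oe = de_list([("g1", 1, 0.01), ("g2", 1, 0.5)])
        kd = de_list([("g1", 1, 0.01), ("g2", -1, 0.01)])
        with caplog.at_level("WARNING"):
            core = core_regulated_set(oe, kd)
        assert len(core) == 0

    def test_threshold_semantics(self):
        oe = de_list([("g1", 1, 0.06)])
        kd = de_list([("g1", -1, 0.01)])
        assert len(core_regulated_set(oe, kd, 0.05)) == 0
        assert core_regulated_set(oe, kd, 0.10).gene_ids == {"g1"}

    def test_mismatched_universe(self):
        oe = de_list([("g1", 1, 0.01)])
        kd = de_list([("g2", -1, 0.01)])
        with pytest.raises(ValueError, match="2"):
            core_regulated_set(oe, kd)

    def test_monotone_in_threshold(self, rng):
        genes = [f"g{i}" for i in range(50)]
        oe = de_list([(g, rng.normal(), rng.random()) for g in genes])
        kd = de_list([(g, rng.normal(), rng.random()) for g in genes])
        tight = core_regulated_set(oe, kd, 0.05).gene_ids
        loose = core_regulated_set(oe, kd, 0.10).gene_ids
        assert tight <= loose


class TestSetOverlapSummary:
    def test_printed_sizes_give_19_pct(self):
        a = GeneSet("ad", [f"g{i}" for i in range(1825)])
        b = GeneSet("cr", [f"g{i}" for i in range(1825 - 316, 1825 - 316 + 1655)])
        s = set_overlap_summary(a, b)
        assert s.n_overlap == 316
        assert s.pct_rounded == 19

    def test_identical_sets(self):
        a = GeneSet("a", [f"g{i}" for i in range(10)])
        s = set_overlap_summary(a, a)
        assert s.pct_rounded == 100

    def test_disjoint(self):
        a = GeneSet("a", ["x"])
        b = GeneSet("b", ["y"])
        assert set_overlap_summary(a, b).pct_rounded == 0

    def test_symmetric(self):
        a = GeneSet("a", [f"g{i}" for i in range(20)])
        b = GeneSet("b", [f"g{i}" for i in range(10, 40)])
        s1, s2 = set_overlap_summary(a, b), set_overlap_summary(b, a)
        assert s1.n_overlap == s2.n_overlap
        assert s1.pct_overlap == s2.pct_overlap

    def test_both_empty_error(self):
        with pytest.raises(ValueError):
            set_overlap_summary(GeneSet("a", []), GeneSet("b", []))


class TestSignatureProjection:
    def _planted(self, rng, effect=3.0):
        n_genes, n_sig = 60, 20
        samples = [f"s{i}" for i in range(12)]
        truth = {s: ("A" if i < 6 else "B") for i, s in enumerate(samples)}
        vals = rng.normal(0, 1, size=(n_genes, 12))
        # signature genes separate the groups, half up and half down in B
        # (a uniform shift would be invisible to correlation distance)
        signs = np.where(np.arange(n_sig) % 2 == 0, 1.0, -1.0)
        vals[:n_sig, 6:] += effect * signs[:, None]
        m = ExpressionMatrix([f"g{i}" for i in range(n_genes)], samples, vals)
        sig = GeneSet("sig", [f"g{i}" for i in range(n_sig)])
        return m, sig, truth

    def test_planted_partition_ari_one(self, rng):
        m, sig, truth = self._planted(rng)
        _, _, ari = signature_projection(m, sig, 2, true_labels=truth)
        assert ari == pytest.approx(1.0)

    def test_disjoint_signature_error(self, rng):
        m, _, _ = self._planted(rng)
        with pytest.raises(ValueError):
            signature_projection(m, GeneSet("x", ["nope1", "nope2"]), 2)

    def test_k_equals_n_samples(self, rng):
        m, sig, truth = self._planted(rng)
        order, labels, ari = signature_projection(
            m, sig, k=12, true_labels=truth
        )
        assert len(set(labels.values())) == 12
        assert ari is not None

    def test_missing_genes_logged(self, rng, caplog):
        m, sig, _ = self._planted(rng)
        bigger = GeneSet("sig+", list(sig.gene_ids) + ["absent1", "absent2"])
        with caplog.at_level("WARNING"):
            signature_projection(m, bigger, 2)
        assert "2 of 22" in caplog.text


class TestIO:
    def test_matrix_roundtrip(self, tmp_path, rng):
        m = make_matrix(rng.normal(8, 1, (10, 4)),
                        groups={f"s{j}": "grp" for j in range(4)})
        write_expression_tsv(m, tmp_path / "e.tsv", tmp_path / "g.tsv")
        back = read_expression_tsv(tmp_path / "e.tsv", tmp_path / "g.tsv")
        assert back.gene_ids == m.gene_ids
        assert np.allclose(back.values, m.values)
        assert back.groups == m.groups

    def test_gene_set_roundtrip(self, tmp_path):
        gs = GeneSet("s", ["b", "a"], provenance="test fixture")
        write_gene_set(gs, tmp_path / "s.txt")
        back = read_gene_set(tmp_path / "s.txt")
        assert back.gene_ids == gs.gene_ids
        assert "test fixture" in back.provenance
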