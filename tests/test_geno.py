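"""Genotype QC, HWE exact test, LD pruning/clumping, PCA, SV score."""

import numpy as np
import pytest
from scipy.special import comb

from teqtl.geno import (
    annotate_qc,
    clump_by_pvalue,
    genotype_pca,
    hwe_exact_test,
    ld_r2,
    net_te_copy_number,
    prune_ld,
    qc_filter_variants,
    read_dosage_tsv,
    SVRecord,
)
from teqtl.simulate import SimConfig, simulate_genotypes

from conftest import make_genotypes


def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Brute-force exact HWE p: enumerate all het configs at fixed allele counts."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_alt, 2 * n - n_alt)
    if rare == 0:
        return 1.0
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        # multinomial coefficient x 2^h (unnormalized conditional likelihood)
        probs[h] = comb(n, h, exact=True) * comb(n - h, hom_rare, exact=True) * 2**h
    total = sum(probs.values())
    observed = probs[n_het]
    return sum(v for v in probs.values() if v <= observed) / total


class TestHweExactTest:
    def test_monomorphic_site_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 50) == 1.0

    def test_extreme_het_excess_below_filter_threshold(self):
        assert hwe_exact_test(0, 50, 0) == pytest.approx(
            hwe_enumeration_oracle(0, 50, 0), abs=1e-12
        )
        assert hwe_exact_test(0, 50, 0) < 1e-6

    @pytest.mark.parametrize(
        "counts", [(5, 10, 5), (10, 5, 10), (20, 10, 1), (1, 1, 1), (0, 3, 12)]
    )
    def test_matches_enumeration(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12
        )

    def test_all_configurations_up_to_n50(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n - a + 1))
            c = n - a - b
            assert hwe_exact_test(a, b, c) == pytest.approx(
                hwe_enumeration_oracle(a, b, c), abs=1e-12
            )

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError, match="empty"):
            hwe_exact_test(0, 0, 0)


class TestQcFilter:
    def test_hand_maf(self):
        g = make_genotypes(np.array([[0], [0], [1], [2]]))
        out = qc_filter_variants(g)
        assert out.n_variants == 1
        assert out.variants["maf"].iloc[0] == pytest.approx(3 / 8)

    def test_monomorphic_removed(self):
        g = make_genotypes(np.array([[0, 0], [0, 1], [0, 2], [0, 1]]))
        out = qc_filter_variants(g)
        assert list(out.variants["id"]) == ["v1"]

    def test_matches_naive_loop_on_panel(self):
        g, _, _ = simulate_genotypes(SimConfig(n_samples=80, n_snvs=1000, seed=3))
        out = qc_filter_variants(g, maf_min=0.1, hwe_p_min=1e-3)
        survivors = []
        for j in range(g.n_variants):
            col = g.dosage[:, j]
            freq = col.mean() / 2
            maf = min(freq, 1 - freq)
            p = hwe_enumeration_oracle(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            )
            if maf >= 0.1 and p >= 1e-3:
                survivors.append(g.variants["id"].iloc[j])
        assert list(out.variants["id"]) == survivors

    def test_idempotent(self):
        g, _, _ = simulate_genotypes(SimConfig(n_samples=50, n_snvs=200, seed=4))
        once = qc_filter_variants(g)
        twice = qc_filter_variants(once)
        assert list(once.variants["id"]) == list(twice.variants["id"])
        np.testing.assert_array_equal(once.dosage, twice.dosage)

    def test_all_removed_warns_not_errors(self):
        g = make_genotypes(np.zeros((6, 2)))
        with pytest.warns(UserWarning, match="all variants"):
            out = qc_filter_variants(g)
        assert out.n_variants == 0


class TestLdR2:
    def test_identical_vectors(self):
        v = np.array([0, 1, 2, 1, 0])
        assert ld_r2(v, v) == pytest.approx(1.0)

    def test_orthogonal_by_construction(self):
        assert ld_r2([0, 2, 0, 2], [0, 0, 2, 2]) == pytest.approx(0.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 30).astype(float)
        b = rng.integers(0, 3, 30).astype(float)
        expected = (np.cov(a, b)[0, 1] / (a.std(ddof=1) * b.std(ddof=1))) ** 2
        assert ld_r2(a, b) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            ld_r2([1, 1, 1, 1], [0, 1, 2, 1])


def prune_reference_oracle(g, window, step, r2_max):
    """Independent re-statement of the sliding-window greedy pruning rule."""
    ann = annotate_qc(g)
    maf = ann.variants["maf"].to_numpy()
    chrom = ann.variants["chrom"].to_numpy()
    alive = [True] * ann.n_variants
    start = 0
    while start < ann.n_variants:
        while True:
            live = [
                j for j in range(start, min(start + window, ann.n_variants)) if alive[j]
            ]
            offender = None
            for x in range(len(live)):
                for y in range(x + 1, len(live)):
                    i, j = live[x], live[y]
                    if chrom[i] != chrom[j]:
                        continue
                    a, b = ann.dosage[:, i].astype(float), ann.dosage[:, j].astype(float)
                    if a.std() == 0 or b.std() == 0:
                        continue
                    if np.corrcoef(a, b)[0, 1] ** 2 > r2_max:
                        offender = (i, j)
                        break
                if offender:
                    break
            if offender is None:
                break
            i, j = offender
            victim = i if maf[i] < maf[j] else j
            alive[victim] = False
        start += step
    return [ann.variants["id"].iloc[j] for j in range(ann.n_variants) if alive[j]]


class TestPruneLd:
    def test_uncorrelated_panel_identity(self):
        rng = np.random.default_rng(2)
        g = make_genotypes(rng.integers(0, 3, (60, 12)))
        out = prune_ld(g, r2_max=0.999)
        assert out.n_variants == 12

    def test_duplicated_column_one_removed(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 3, 40)
        g = make_genotypes(np.column_stack([col, col]))
        out = prune_ld(g)
        assert out.n_variants == 1

    def test_matches_reference_greedy_loop(self):
        g, _, _ = simulate_genotypes(
            SimConfig(n_samples=60, n_snvs=60, ld_rho=0.8, seed=5)
        )
        out = prune_ld(g, window=20, step=5, r2_max=0.1)
        assert list(out.variants["id"]) == prune_reference_oracle(g, 20, 5, 0.1)

    def test_unsorted_variants_error(self):
        g = make_genotypes(
            np.random.default_rng(0).integers(0, 3, (20, 3)), pos=[5000, 1000, 3000]
        )
        with pytest.raises(ValueError, match="sorted"):
            prune_ld(g)


class TestClumpByPvalue:
    def _panel(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 3, 100)
        noise = rng.integers(0, 3, 100)
        b = np.where(rng.random(100) < 0.7, a, noise)  # correlated with a
        c = rng.integers(0, 3, 100)  # independent
        g = make_genotypes(
            np.column_stack([a, b, c]), pos=[1000, 2000, 3000], ids=["A", "B", "C"]
        )
        assert ld_r2(a, b) > 0.1 and ld_r2(a, c) < 0.1 and ld_r2(b, c) < 0.1
        return g

    def test_hand_run_of_greedy_rule(self):
        g = self._panel()
        clumps = clump_by_pvalue({"A": 1e-8, "B": 1e-6, "C": 1e-7}, g)
        by_index = {c.index_snv: sorted(c.members) for c in clumps}
        assert set(by_index) == {"A", "C"}
        assert by_index["A"] == ["A", "B"]
        assert by_index["C"] == ["C"]
        assert {c.index_snv: c.index_p for c in clumps} == {"A": 1e-8, "C": 1e-7}

    def test_single_variant_is_own_index(self):
        g = make_genotypes(
            np.random.default_rng(0).integers(0, 3, (30, 1)), ids=["X"]
        )
        clumps = clump_by_pvalue({"X": 0.01}, g)
        assert len(clumps) == 1 and clumps[0].index_snv == "X"

    def test_no_ld_all_singletons(self):
        rng = np.random.default_rng(9)
        g = make_genotypes(rng.integers(0, 3, (200, 5)))
        clumps = clump_by_pvalue(
            {f"v{j}": p for j, p in enumerate([0.1, 0.2, 0.01, 0.5, 0.3])},
            g, r2_min=0.5,
        )
        assert len(clumps) == 5

    def test_partition_and_index_dominance(self):
        g, _, _ = simulate_genotypes(
            SimConfig(n_samples=100, n_snvs=80, ld_rho=0.8, seed=6)
        )
        rng = np.random.default_rng(1)
        p = {v: float(x) for v, x in zip(g.variants["id"], rng.random(80))}
        clumps = clump_by_pvalue(p, g)
        members = [m for c in clumps for m in c.members]
        assert sorted(members) == sorted(p)  # partition
        meta = g.variants.set_index("id")
        for c in clumps:
            for m in c.members:
                assert p[c.index_snv] <= p[m]
                if m != c.index_snv:
                    assert meta.loc[m, "chrom"] == meta.loc[c.index_snv, "chrom"]
                    assert abs(meta.loc[m, "pos"] - meta.loc[c.index_snv, "pos"]) <= 500_000
                    assert ld_r2(g.dosage_of(m), g.dosage_of(c.index_snv)) > 0.1

    def test_missing_variant_named_in_error(self):
        g = make_genotypes(np.random.default_rng(0).integers(0, 3, (20, 2)))
        with pytest.raises(KeyError, match="ghost"):
            clump_by_pvalue({"v0": 0.1, "ghost": 0.2}, g)


class TestGenotypePca:
    def test_scores_match_eigendecomposition(self):
        rng = np.random.default_rng(10)
        g = make_genotypes(rng.integers(0, 3, (5, 4)))
        scores = genotype_pca(g, 2)
        x = g.dosage.astype(float)
        x = (x - x.mean(0)) / x.std(0)
        eigval, eigvec = np.linalg.eigh(x @ x.T)
        order = np.argsort(eigval)[::-1]
        for k in range(2):
            expected = x @ (x.T @ eigvec[:, order[k]])
            expected = eigvec[:, order[k]] * np.sqrt(eigval[order[k]])
            np.testing.assert_allclose(
                np.abs(scores.iloc[:, k]), np.abs(expected), atol=1e-8
            )

    def test_orthogonal_scores(self):
        g, _, _ = simulate_genotypes(SimConfig(n_samples=60, n_snvs=150, seed=12))
        scores = genotype_pca(g, 4).to_numpy()
        gram = scores.T @ scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)

    def test_two_populations_separate_on_pc1(self):
        g, _, labels = simulate_genotypes(
            SimConfig(n_samples=200, n_snvs=2000, fst=0.1, ld_rho=0.0, seed=13)
        )
        pc1 = genotype_pca(g, 2)["PC1"].to_numpy()
        a, b = pc1[labels == 0], pc1[labels == 1]
        between = abs(a.mean() - b.mean())
        within = (a.std() + b.std()) / 2
        assert between > within

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(14)
        dosage = rng.integers(0, 3, (20, 4))
        dosage[:, 2] = 1
        g = make_genotypes(dosage)
        scores = genotype_pca(g, 2)
        assert scores.shape == (20, 2)
        assert np.isfinite(scores.to_numpy()).all()

    def test_too_many_pcs_error(self):
        g = make_genotypes(np.random.default_rng(0).integers(0, 3, (4, 3)))
        with pytest.raises(ValueError, match="n_pcs"):
            genotype_pca(g, 4)


class TestNetTeCopyNumber:
    def test_hand_sum(self):
        svs = [
            SVRecord("i1", "L1_insertion", np.array([1])),
            SVRecord("i2", "Alu_insertion", np.array([2])),
            SVRecord("d1", "L1_deletion", np.array([1])),
            SVRecord("d2", "Alu_deletion", np.array([0])),
        ]
        assert net_te_copy_number(svs)[0] == 2

    def test_other_class_ignored(self):
        svs = [SVRecord("o", "other", np.array([2, 2]))]
        np.testing.assert_array_equal(net_te_copy_number(svs), [0, 0])

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(15)
        classes = ["L1_insertion", "L1_deletion", "Alu_insertion", "Alu_deletion", "other"]
        svs = [
            SVRecord(f"sv{i}", classes[i % 5], rng.integers(0, 3, 12))
            for i in range(25)
        ]
        expected = np.zeros(12, dtype=int)
        for sv in svs:
            for j in range(12):
                if "insertion" in sv.sv_class and sv.sv_class != "other":
                    expected[j] += sv.dosage[j]
                elif "deletion" in sv.sv_class:
                    expected[j] -= sv.dosage[j]
        np.testing.assert_array_equal(net_te_copy_number(svs), expected)


class TestDosageRoundTrip:
    def test_tsv_round_trip(self, tmp_path):
        g, _, _ = simulate_genotypes(SimConfig(n_samples=20, n_snvs=30, seed=16))
        g.to_dosage_tsv(tmp_path / "d.tsv")
        g.to_variant_tsv(tmp_path / "v.tsv")
        back = read_dosage_tsv(tmp_path / "d.tsv", tmp_path / "v.tsv")
        assert back.samples == g.samples
        np.testing.assert_array_equal(back.dosage, g.dosage)
        assert list(back.variants["pos"]) == list(g.variants["pos"])
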