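"""Informativeness for assignment, PCA and classical MDS."""

import math

import numpy as np
import pandas as pd
import pytest

from forenpop.io_formats import AlleleFrequencyTable, DistanceMatrix
from forenpop.population_structure import (
    classical_mds,
    in_table,
    informativeness_in,
    one_vs_rest_in,
    pca_individuals,
    pca_populations,
)
from forenpop.synthetic_data import (
    default_marker_panel,
    simulate_genotypes,
    simulate_snp_frequencies,
)


class TestInformativeness:
    def test_identical_groups_zero(self):
        f = {"a": 0.3, "b": 0.7}
        assert informativeness_in([f, f, f]) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_groups_ln2(self):
        assert informativeness_in([{"a": 1.0}, {"b": 1.0}]) == pytest.approx(
            math.log(2)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_direct_summation_oracle(self, seed):
        """Term-by-term brute-force of the formula on 3-group biallelic."""
        rng = np.random.default_rng(seed)
        groups = [
            {"a": p, "b": 1 - p} for p in rng.uniform(0.05, 0.95, size=3)
        ]
        K = 3

        def xlogx(p):
            return 0.0 if p == 0 else p * math.log(p)

        brute = 0.0
        for allele in ("a", "b"):
            pbar = sum(g[allele] for g in groups) / K
            brute += -xlogx(pbar)
            for g in groups:
                brute += xlogx(g[allele]) / K
        assert informativeness_in(groups) == pytest.approx(brute, abs=1e-12)

    def test_relabeling_and_zero_allele_invariance(self):
        groups = [{"a": 0.2, "b": 0.8}, {"a": 0.6, "b": 0.4}]
        relabeled = [{"x": 0.2, "y": 0.8}, {"x": 0.6, "y": 0.4}]
        padded = [
            {"a": 0.2, "b": 0.8, "c": 0.0},
            {"a": 0.6, "b": 0.4, "c": 0.0},
        ]
        base = informativeness_in(groups)
        assert informativeness_in(relabeled) == pytest.approx(base, abs=1e-12)
        assert informativeness_in(padded) == pytest.approx(base, abs=1e-12)

    def test_bounded_by_ln_k(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            K = int(rng.integers(2, 6))
            groups = [
                dict(zip("abcd", rng.dirichlet([0.5] * 4))) for _ in range(K)
            ]
            v = informativeness_in(groups)
            assert 0.0 <= v <= math.log(K) + 1e-12


class TestOneVsRest:
    def test_target_equal_to_pooled_rest_zero(self):
        f = {"a": 0.4, "b": 0.6}
        groups = {"t": dict(f), "r1": dict(f), "r2": dict(f)}
        sizes = {"t": 100, "r1": 50, "r2": 150}
        assert one_vs_rest_in(groups, "t", sizes) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_target_ln2(self):
        groups = {"t": {"a": 1.0}, "r": {"b": 1.0}}
        assert one_vs_rest_in(groups, "t", {"t": 10, "r": 10}) == pytest.approx(
            math.log(2)
        )

    def test_pooling_weighted_by_chromosomes(self):
        groups = {
            "t": {"a": 0.5, "b": 0.5},
            "r1": {"a": 1.0, "b": 0.0},
            "r2": {"a": 0.0, "b": 1.0},
        }
        # rest pooled 3:1 → {a: 0.75, b: 0.25}
        v = one_vs_rest_in(groups, "t", {"t": 100, "r1": 150, "r2": 50})
        expected = informativeness_in(
            [{"a": 0.5, "b": 0.5}, {"a": 0.75, "b": 0.25}]
        )
        assert v == pytest.approx(expected, abs=1e-12)

    def test_divergent_group_has_max_one_vs_rest(self):
        """In a 5-group set with one outlier, that group's one-vs-rest
        I_n is the largest."""
        f_map = {f"g{i}": 0.01 for i in range(4)}
        f_map["out"] = 0.30
        freqs = simulate_snp_frequencies(
            np.full(40, 0.5), f_map, seed=3, n_chromosomes=180
        )
        tbl = in_table(freqs, contrasts="one_vs_rest")
        mean_by_group = (
            tbl.assign(group=tbl["contrast"].str.split(":").str[1])
            .groupby("group")["In"]
            .mean()
        )
        assert mean_by_group.idxmax() == "out"

    def test_continuity_toward_pooled_rest(self):
        base = {"a": 0.4, "b": 0.6}
        sizes = {"t": 100, "r": 100}
        vals = []
        for eps in (0.2, 0.1, 0.01, 0.001):
            groups = {"t": {"a": 0.4 + eps, "b": 0.6 - eps}, "r": dict(base)}
            vals.append(one_vs_rest_in(groups, "t", sizes))
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-5


class TestPCA:
    def _freq_table(self, mat, pops):
        rows = []
        for pop, row in zip(pops, mat):
            for j, p in enumerate(row):
                rows.append((pop, f"L{j}", "a", float(p), 100))
                rows.append((pop, f"L{j}", "b", float(1 - p), 100))
        return AlleleFrequencyTable(
            pd.DataFrame(
                rows, columns=["population", "locus", "allele", "frequency", "n"]
            )
        )

    def test_identical_populations_coincide(self):
        mat = np.array([[0.3, 0.6], [0.3, 0.6], [0.8, 0.1]])
        res = pca_populations(self._freq_table(mat, ["p1", "p2", "p3"]))
        np.testing.assert_allclose(
            res.coordinates[0], res.coordinates[1], atol=1e-12
        )

    def test_variance_fractions_sum_to_one_full_rank(self):
        rng = np.random.default_rng(0)
        mat = rng.uniform(0.1, 0.9, size=(4, 6))
        res = pca_populations(self._freq_table(mat, [f"p{i}" for i in range(4)]))
        assert res.explained.sum() == pytest.approx(1.0)
        assert (np.diff(res.explained) <= 1e-12).all()

    def test_scores_preserve_centered_geometry(self):
        """Row distances of the scores equal those of the centered data
        (SVD is an isometry), the full-rank reconstruction identity."""
        rng = np.random.default_rng(2)
        mat = rng.uniform(0.1, 0.9, size=(5, 8))
        res = pca_populations(self._freq_table(mat, [f"p{i}" for i in range(5)]))
        ft = self._freq_table(mat, [f"p{i}" for i in range(5)]).to_matrix()
        x = ft.to_numpy() - ft.to_numpy().mean(axis=0)
        d_data = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        s = res.coordinates
        d_scores = np.linalg.norm(s[:, None] - s[None, :], axis=2)
        np.testing.assert_allclose(d_scores, d_data, atol=1e-10)

    def test_constant_matrix_all_zero(self):
        mat = np.full((3, 4), 0.5)
        res = pca_populations(self._freq_table(mat, ["p1", "p2", "p3"]))
        assert np.allclose(res.coordinates, 0.0)
        assert np.allclose(res.explained, 0.0)

    def test_individual_level_clones_identical(self):
        from forenpop.io_formats import GenotypeTable, LocusSpec

        loci = [LocusSpec(f"rs{i}", "IISNP") for i in range(5)]
        cells = {}
        genos = [("A", "G"), ("A", "A"), ("G", "G"), ("A", "G"), ("A", "A")]
        for s in ("c1", "c2"):
            for spec, g in zip(loci, genos):
                cells[(s, spec.name)] = g
        for spec, g in zip(loci, [("G", "G")] * 5):
            cells[("other", spec.name)] = g
        t = GenotypeTable(
            samples=["c1", "c2", "other"],
            populations=["p"] * 3,
            loci=loci,
            cells=cells,
        )
        res = pca_individuals(t, scale=False)
        np.testing.assert_allclose(
            res.coordinates[0], res.coordinates[1], atol=1e-12
        )

    def test_two_diverged_populations_separate_on_pc1(self):
        """Balding–Nichols F=0.1, 100 SNPs, 50+50 individuals: PC1 sign
        classifies population with > 95% accuracy."""
        from forenpop.io_formats import LocusSpec

        loci = [f"rs{i:03d}" for i in range(100)]
        specs = [LocusSpec(l, "IISNP") for l in loci]
        freqs = simulate_snp_frequencies(
            np.random.default_rng(0).uniform(0.2, 0.8, size=100),
            {"p1": 0.1, "p2": 0.1},
            seed=9,
            loci=loci,
        )
        table = simulate_genotypes(freqs, {"p1": 50, "p2": 50}, specs, seed=10)
        res = pca_individuals(table)
        pc1 = res.coordinates[:, 0]
        labels = np.array(table.populations)
        sign_groups = [np.sign(pc1[labels == p]) for p in ("p1", "p2")]
        acc = max(
            (np.mean(sign_groups[0] > 0) + np.mean(sign_groups[1] < 0)) / 2,
            (np.mean(sign_groups[0] < 0) + np.mean(sign_groups[1] > 0)) / 2,
        )
        assert acc > 0.95

    def test_dosage_centering(self):
        from forenpop.population_structure import dosage_matrix
        from forenpop.io_formats import GenotypeTable, LocusSpec

        loci = [LocusSpec("rs1", "IISNP")]
        t = GenotypeTable(
            samples=["a", "b"],
            populations=["p", "p"],
            loci=loci,
            cells={("a", "rs1"): ("A", "G"), ("b", "rs1"): ("G", "G")},
        )
        dm = dosage_matrix(t)
        centered = dm.to_numpy() - dm.to_numpy().mean(axis=0)
        assert np.allclose(centered.mean(axis=0), 0.0)


class TestMDS:
    def test_two_points(self):
        m = DistanceMatrix(labels=["A", "B"], values=[[0, 3.0], [3.0, 0]])
        res = classical_mds(m, k=1)
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-1.5, 1.5])

    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        m = DistanceMatrix(labels=[f"x{i}" for i in range(7)], values=d)
        res = classical_mds(m, k=2)
        # Procrustes: compare centered configurations up to rotation
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, res.coordinates)
        assert disparity < 1e-8

    def test_all_zero_matrix(self):
        m = DistanceMatrix(labels=["A", "B", "C"], values=np.zeros((3, 3)))
        res = classical_mds(m, k=2)
        assert np.allclose(res.coordinates, 0.0)

    def test_negative_entries_floored(self):
        vals = np.array([[0, -0.005, 0.3], [-0.005, 0, 0.3], [0.3, 0.3, 0]])
        m = DistanceMatrix(labels=["A", "B", "C"], values=vals, metric="RST")
        with pytest.warns(UserWarning, match="reducing k"):
            res = classical_mds(m, k=2)
        # A and B behave as coincident after flooring
        assert np.linalg.norm(res.coordinates[0] - res.coordinates[1]) < 1e-9

    def test_k_reduced_with_warning(self):
        m = DistanceMatrix(labels=["A", "B"], values=[[0, 1.0], [1.0, 0]])
        with pytest.warns(UserWarning, match="reducing k"):
            res = classical_mds(m, k=2)
        assert res.coordinates.shape[1] == 1

    def test_mds_of_pca_scores_reproduces_them(self):
        """MDS on Euclidean distances between PCA scores recovers the
        scores up to an orthogonal transform."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=(6, 3))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        res = classical_mds(
            DistanceMatrix(labels=[f"e{i}" for i in range(6)], values=d), k=3
        )
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(x - x.mean(axis=0), res.coordinates)
        assert disparity < 1e-10
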