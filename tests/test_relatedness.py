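"""KING-robust kinship, genotype PCA, and the kinship dendrogram."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from clonediv.features import EXON, INTRON, NONREP, REPEAT
from clonediv.relatedness import (KinshipUndefinedError, genotype_matrix,
                                  genotype_pca, king_phi, kinship_dendrogram,
                                  kinship_matrix,
                                  simulate_hardy_weinberg_pair)
from clonediv.simulate import simulate

from conftest import CLONES, small_config
from _oracles import naive_average_linkage


class TestKingPhi:
    def test_self_kinship_is_exactly_half(self):
        g = np.array([0, 1, 1, 2, 0, 1], dtype=np.int8)
        assert king_phi(g, g) == 0.5

    def test_hand_fixture_evaluates_to_zero(self):
        # both-het at 2 sites, opposite homozygotes at 1, het counts 4 and 2
        gi = np.array([1, 1, 1, 1, 0, 2], dtype=np.int8)
        gj = np.array([1, 1, 0, 0, 2, 2], dtype=np.int8)
        assert sum(gi == 1) == 4 and sum(gj == 1) == 2
        assert king_phi(gi, gj) == pytest.approx(0.0)

    def test_no_hets_is_undefined(self):
        gi = np.array([0, 2, 0], dtype=np.int8)
        gj = np.array([0, 0, 2], dtype=np.int8)
        with pytest.raises(KinshipUndefinedError):
            king_phi(gi, gj)

    def test_missing_sites_are_pairwise_excluded(self):
        gi = np.array([1, 1, -1, 1], dtype=np.int8)
        gj = np.array([1, -1, 1, 1], dtype=np.int8)
        # shared sites: 0 and 3, both het-het
        assert king_phi(gi, gj) == 0.5

    def test_unrelated_hardy_weinberg_pair_near_zero(self):
        m = simulate_hardy_weinberg_pair(50_000, seed=42)
        phi = king_phi(m.loc["ind1"].to_numpy(), m.loc["ind2"].to_numpy())
        assert abs(phi) <= 0.02

    def test_parent_offspring_near_quarter(self):
        rng = np.random.default_rng(43)
        n = 30_000
        p = rng.uniform(0.05, 0.5, size=n)
        parent = rng.binomial(2, p, size=n)
        transmitted = np.where(parent == 1, rng.integers(0, 2, size=n),
                               parent // 2)
        child = transmitted + rng.binomial(1, p, size=n)
        phi = king_phi(parent.astype(np.int8), child.astype(np.int8))
        assert phi == pytest.approx(0.25, abs=0.03)

    def test_clone_pair_approaches_half_as_private_load_vanishes(self):
        # shared het background H, clone adds m private hets: PHI = H/(2H+m)
        H = 1000
        prev = None
        for m in (400, 100, 10, 0):
            mother = np.concatenate([np.ones(H), np.zeros(m)]).astype(np.int8)
            clone = np.concatenate([np.ones(H), np.ones(m)]).astype(np.int8)
            phi = king_phi(mother, clone)
            assert phi == pytest.approx(H / (2 * H + m))
            if prev is not None:
                assert phi > prev
            prev = phi
        assert prev == 0.5


class TestKinshipMatrix:
    def test_duplicated_sample_pair_is_self(self):
        m = simulate_hardy_weinberg_pair(2_000, seed=44)
        m.loc["dup"] = m.loc["ind1"]
        kin = kinship_matrix(m)
        assert kin.loc["ind1", "dup"] == 0.5
        assert np.allclose(kin.values, kin.values.T)
        assert (np.diag(kin.values) == 0.5).all()

    def test_undefined_pair_reported_nan(self, caplog):
        m = pd.DataFrame([[0, 2], [2, 0], [1, 1]],
                         index=["a", "b", "c"], columns=["s1", "s2"])
        with caplog.at_level("WARNING"):
            kin = kinship_matrix(m)
        assert np.isnan(kin.loc["a", "b"])
        # a has no hets: the pair leans entirely on c's two hets
        assert kin.loc["a", "c"] == pytest.approx(0.0)
        assert kin.loc["c", "c"] == 0.5

    def test_clone_panel_kinship_range(self, default_dataset):
        """Clones differing by private somatic hets against a large shared
        ancestral background sit just below self-kinship."""
        gmat = genotype_matrix(default_dataset.variants, samples=CLONES)
        kin = kinship_matrix(gmat)
        off = kin.values[np.triu_indices(len(CLONES), 1)]
        assert (off > 0.3).all() and (off < 0.5).all()

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            kinship_matrix(pd.DataFrame([[1, 0]], index=["a"]))


class TestPCA:
    def test_identical_samples_identical_coordinates(self):
        rng = np.random.default_rng(45)
        base = rng.integers(0, 3, size=200)
        m = pd.DataFrame([base, base, 2 - base],
                         index=["a", "b", "c"])
        coords, _ = genotype_pca(m)
        assert np.allclose(coords.loc["a"], coords.loc["b"])

    def test_two_subclades_separate_on_pc1(self):
        sub = (tuple(CLONES[:8]), tuple(CLONES[8:]))
        ds = simulate(small_config(
            23, contig_length=20000, subclade_spec=sub,
            subclade_event_fraction=0.8))
        gmat = genotype_matrix(ds.variants, samples=CLONES)
        coords, _ = genotype_pca(gmat)
        pc1 = coords["PC1"]
        a, b = pc1[list(sub[0])], pc1[list(sub[1])]
        # the clusters occupy disjoint intervals on PC1
        assert a.min() > b.max() or b.min() > a.max()
        assert (a.mean() - b.mean()) ** 2 > 4 * (a.var() + b.var())

    def test_site_permutation_invariance_up_to_sign(self):
        rng = np.random.default_rng(46)
        m = pd.DataFrame(rng.integers(0, 3, size=(6, 300)),
                         index=list("abcdef"))
        perm = rng.permutation(m.shape[1])
        c1, _ = genotype_pca(m)
        c2, _ = genotype_pca(m.iloc[:, perm])
        for col in c1.columns:
            assert (np.allclose(c1[col], c2[col], atol=1e-8)
                    or np.allclose(c1[col], -c2[col], atol=1e-8))

    def test_constant_matrix_degenerate(self):
        m = pd.DataFrame(np.ones((3, 10), dtype=np.int8),
                         index=list("abc"))
        with pytest.raises(ValueError):
            genotype_pca(m)


class TestDendrogram:
    def _kin(self, values, labels):
        return pd.DataFrame(values, index=labels, columns=labels)

    def test_closest_pair_joins_first(self):
        kin = self._kin(
            [[0.5, 0.45, 0.05], [0.45, 0.5, 0.05], [0.05, 0.05, 0.5]],
            ["s1", "s2", "s3"])
        z, newick = kinship_dendrogram(kin)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}
        assert newick.startswith("((") or "(s1:" in newick

    def test_equal_phi_gives_equal_heights(self):
        kin = self._kin(np.full((3, 3), 0.2) + np.eye(3) * 0.3,
                        ["s1", "s2", "s3"])
        z, _ = kinship_dendrogram(kin)
        assert z[0, 2] == pytest.approx(z[1, 2])

    def test_merge_order_matches_naive_agglomeration(self):
        rng = np.random.default_rng(47)
        n = 8
        phi = rng.uniform(0.0, 0.45, size=(n, n))
        phi = (phi + phi.T) / 2
        np.fill_diagonal(phi, 0.5)
        labels = [f"s{i}" for i in range(n)]
        kin = self._kin(phi, labels)
        z, _ = kinship_dendrogram(kin)
        dist = 0.5 - phi
        np.fill_diagonal(dist, 0.0)
        merges = naive_average_linkage(dist)
        # scipy merge heights equal the naive agglomeration heights, in order
        assert np.allclose(z[:, 2], [h for _, _, h in merges])
        # and the same clusters form
        scipy_sets = _linkage_member_sets(z, n)
        naive_sets = [a | b for a, b, _ in merges]
        assert scipy_sets == naive_sets

    def test_phi_above_half_clips_with_warning(self, caplog):
        kin = self._kin(
            [[0.5, 0.55, 0.1], [0.55, 0.5, 0.1], [0.1, 0.1, 0.5]],
            ["s1", "s2", "s3"])
        with caplog.at_level("WARNING"):
            z, _ = kinship_dendrogram(kin)
        assert (z[:, 2] >= 0).all()

    def test_newick_is_parseable(self, default_dataset):
        import io
        from Bio import Phylo
        gmat = genotype_matrix(default_dataset.variants, samples=CLONES)
        _, newick = kinship_dendrogram(kinship_matrix(gmat))
        tree = Phylo.read(io.StringIO(newick), "newick")
        assert {t.name for t in tree.get_terminals()} == set(CLONES)


def _linkage_member_sets(z, n):
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, _, _) in enumerate(z):
        s = members[int(a)] | members[int(b)]
        members[n + k] = s
        out.append(s)
    return out
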