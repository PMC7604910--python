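"""Cluster assignment, subclustering, outliers, symmetry collapse, reindexing."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from xtalcluster import (
    ClusterNode,
    CoordinateModel,
    FixtureSpec,
    MultiDataSet,
    ReflectionSet,
    SymmetryOperator,
    apply_index_op,
    assign_clusters,
    average_coordinates,
    cluster_multidataset,
    collapse_symmetry,
    generate_multidataset,
    operators_from_spacegroup,
    parse_index_op,
    remove_outliers,
    resolve_indexing,
    scale_all,
    subcluster,
)
from xtalcluster.cluster import _apply_symop, index_op_triplet
from xtalcluster.correlation import AxisProjection

CELL = (48.0, 48.0, 60.0, 90.0, 90.0, 90.0)


def blob_projection(rng, centers, per=10, sd=0.01):
    pts, labels, ids = [], [], []
    for ci, c in enumerate(centers):
        for j in range(per):
            pts.append(np.asarray(c) + rng.normal(0, sd, 3))
            labels.append(ci)
            ids.append(f"d{ci}_{j:02d}")
    return AxisProjection((0, 1, 2), np.array(pts), ids), labels


class TestAssignClusters:
    def test_k_one_single_cluster(self, rng):
        proj, _ = blob_projection(rng, [(0, 0, 0)], per=5)
        labels = assign_clusters(proj, k=1, seed=0)
        assert set(labels.values()) == {0}

    def test_planted_blobs_recovered(self, rng):
        proj, truth = blob_projection(rng, [(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        labels = assign_clusters(proj, k=3, seed=0)
        got = [labels[d] for d in proj.labels]
        assert adjusted_rand_score(truth, got) == 1.0

    def test_same_seed_same_labels(self, rng):
        proj, _ = blob_projection(rng, [(0, 0, 0), (1, 1, 1)])
        l1 = assign_clusters(proj, k=2, seed=7)
        l2 = assign_clusters(proj, k=2, seed=7)
        assert l1 == l2

    def test_labels_ordered_by_size_then_first_member(self, rng):
        proj, _ = blob_projection(rng, [(0, 0, 0)], per=4, sd=0.0)
        big = AxisProjection(
            (0, 1, 2),
            np.vstack([proj.s, np.tile([5.0, 5, 5], (7, 1))]),
            proj.labels + [f"z{j}" for j in range(7)],
        )
        labels = assign_clusters(big, k=2, seed=0)
        # the larger cluster (the z's) gets label 0
        assert labels["z0"] == 0 and labels["d0_00"] == 1

    def test_k_exceeding_n_rejected(self, rng):
        proj, _ = blob_projection(rng, [(0, 0, 0)], per=3)
        with pytest.raises(ValueError):
            assign_clusters(proj, k=4, seed=0)

    def test_file_mode_roundtrip(self, rng, tmp_path):
        proj, truth = blob_projection(rng, [(0, 0, 0), (1, 1, 1)], per=3)
        p = tmp_path / "assign.tsv"
        p.write_text("dataset_id\tlabel\n" +
                     "".join(f"{d}\t{t}\n" for d, t in zip(proj.labels, truth)))
        labels = assign_clusters(proj, method="file", path=p)
        assert [labels[d] for d in proj.labels] == truth

    def test_file_missing_ids_rejected(self, rng, tmp_path):
        proj, _ = blob_projection(rng, [(0, 0, 0)], per=3)
        p = tmp_path / "assign.tsv"
        p.write_text("dataset_id\tlabel\nd0_00\t0\n")
        with pytest.raises(ValueError, match="missing"):
            assign_clusters(proj, method="file", path=p)


class TestClusterTree:
    def test_complete_node_cannot_have_children(self):
        with pytest.raises(ValueError, match="complete"):
            ClusterNode(id="r", members=["a"], complete=True,
                        children=[ClusterNode(id="c", members=["a"])])

    def test_children_must_be_subsets(self):
        with pytest.raises(ValueError, match="subset"):
            ClusterNode(id="r", members=["a"],
                        children=[ClusterNode(id="c", members=["b"])])

    def test_dict_roundtrip(self):
        tree = ClusterNode(id="r", members=["a", "b"], mode="reciprocal",
                           axes=(0, 1, 2),
                           children=[ClusterNode(id="r-0", members=["a"]),
                                     ClusterNode(id="r-1", members=["b"])])
        back = ClusterNode.from_dict(tree.to_dict())
        assert back.to_dict() == tree.to_dict()


class TestSubcluster:
    def test_small_subset_marked_complete(self, small_fixture):
        node = ClusterNode(id="r", members=sorted(small_fixture.labels)[:3])
        out = subcluster(node, small_fixture.mds, k=2, min_cluster_size=2)
        assert out.complete and not out.children

    def test_two_level_hierarchy_recovered(self, rng):
        """2 super-groups x 2 subgroups of amplitude perturbations: recursive
        clustering with recalculated averages finds all four leaves."""
        hkl = [(h, k, l) for h in range(-4, 5) for k in range(-4, 5) for l in range(1, 4)]
        n_refl = len(hkl)
        f_base = rng.lognormal(3, 0.4, n_refl)
        super_dirs = rng.standard_normal((2, n_refl))
        sub_dirs = rng.standard_normal((4, n_refl))
        entries, truth = [], {}
        idx = 0
        for g in range(2):
            for sub in range(2):
                for _ in range(8):
                    did = f"ds{idx:03d}"
                    idx += 1
                    truth[did] = 2 * g + sub
                    f = f_base * np.exp(0.20 * super_dirs[g]
                                        + 0.08 * sub_dirs[2 * g + sub]
                                        + 0.01 * rng.standard_normal(n_refl))
                    rs = ReflectionSet(did, np.array(hkl), f, CELL)
                    cm = CoordinateModel(did, ["A/1/"], [[0.0, 0.0, 0.0]])
                    entries.append((rs, cm))
        mds = MultiDataSet(entries)
        scaled = MultiDataSet(list(zip(scale_all(mds.reflection_sets), mds.models)))
        tree, _ = cluster_multidataset(scaled, k=2, seed=0)
        sup = {d: i for i, ch in enumerate(tree.children) for d in ch.members}
        assert adjusted_rand_score([truth[d] // 2 for d in sorted(truth)],
                                   [sup[d] for d in sorted(truth)]) == 1.0
        for child in tree.children:
            subcluster(child, mds, k=2, seed=0, average_policy="recalculate",
                       min_cluster_size=3)
        leaf_label = {d: leaf.id for leaf in tree.leaves() for d in leaf.members}
        ari = adjusted_rand_score([truth[d] for d in sorted(truth)],
                                  [leaf_label[d] for d in sorted(truth)])
        assert ari == 1.0

    def test_inherit_policy_reuses_parent_average(self, small_fixture):
        from xtalcluster import average_amplitudes

        mds = small_fixture.mds
        scaled = MultiDataSet(list(zip(scale_all(mds.reflection_sets), mds.models)))
        parent_avg = average_amplitudes(scaled.reflection_sets)
        node = ClusterNode(id="r", members=mds.dataset_ids[:12])
        out = subcluster(node, scaled, k=2, seed=0, average_policy="inherit",
                         parent_avg=parent_avg, min_cluster_size=3)
        assert out.average_policy == "inherited"
        assert len(out.children) == 2


class TestRemoveOutliers:
    def make_models(self, rng, n=20, atoms=30, noise=0.02):
        base = rng.normal(0, 5, (atoms, 3))
        keys = [f"A/{i}/" for i in range(atoms)]
        return [CoordinateModel(f"d{i:02d}", keys, base + rng.normal(0, noise, (atoms, 3)))
                for i in range(n)]

    def test_identical_models_none_removed(self):
        base = np.arange(30, dtype=float).reshape(10, 3)
        models = [CoordinateModel(f"d{i}", [f"A/{j}/" for j in range(10)], base)
                  for i in range(5)]
        kept, removed = remove_outliers(models, average_coordinates(models))
        assert not removed and len(kept) == 5

    def test_rigidly_shifted_model_removed(self, rng):
        models = self.make_models(rng)
        models[7] = models[7].replace(coords=models[7].coords + 10.0)
        kept, removed = remove_outliers(models, average_coordinates(models))
        assert [m.dataset_id for m in removed] == ["d07"]

    def test_infinite_threshold_removes_nothing(self, rng):
        models = self.make_models(rng)
        models[0] = models[0].replace(coords=models[0].coords + 100.0)
        kept, removed = remove_outliers(models, average_coordinates(models),
                                        threshold_mads=np.inf)
        assert not removed

    def test_needs_three_models(self, rng):
        models = self.make_models(rng, n=2)
        with pytest.raises(ValueError):
            remove_outliers(models, average_coordinates(models))


class TestCollapseSymmetry:
    TWOFOLD = SymmetryOperator(np.diag([-1.0, -1.0, 1.0]), np.zeros(3), "-x,-y,z")
    IDENT = SymmetryOperator(np.eye(3), np.zeros(3), "x,y,z")

    def make_models(self, rng, n=12, atoms=25, noise=0.02):
        base = rng.normal(0, 4, (atoms, 3)) + np.array([10.0, 12.0, 8.0])
        keys = [f"A/{i}/" for i in range(atoms)]
        return [CoordinateModel(f"d{i:02d}", keys, base + rng.normal(0, noise, (atoms, 3)))
                for i in range(n)]

    def test_identity_only_is_noop(self, rng):
        models = self.make_models(rng)
        out, chosen = collapse_symmetry(models, [self.IDENT], CELL)
        for a, b in zip(models, out):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-12)
        assert set(chosen.values()) == {"x,y,z"}

    def test_mixed_frames_collapse_to_noise_level(self, rng):
        models = self.make_models(rng)
        avg0 = average_coordinates(models)
        d0 = max(
            np.linalg.norm(m.coords - avg0.cbar[avg0.positions_of(m.atom_keys)], axis=1).mean()
            for m in models
        )
        mixed = [_apply_symop(m, self.TWOFOLD, CELL) if i % 2 else m
                 for i, m in enumerate(models)]
        out, chosen = collapse_symmetry(mixed, [self.IDENT, self.TWOFOLD], CELL)
        avg = average_coordinates(out)
        for m in out:
            dev = np.linalg.norm(
                m.coords - avg.cbar[avg.positions_of(m.atom_keys)], axis=1).mean()
            assert dev <= d0 + 1e-6

    def test_collapse_is_idempotent(self, rng):
        models = self.make_models(rng)
        mixed = [_apply_symop(m, self.TWOFOLD, CELL) if i % 3 == 0 else m
                 for i, m in enumerate(models)]
        once, _ = collapse_symmetry(mixed, [self.IDENT, self.TWOFOLD], CELL)
        twice, chosen = collapse_symmetry(once, [self.IDENT, self.TWOFOLD], CELL)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-9)
        assert set(chosen.values()) == {"x,y,z"}

    def test_never_increases_deviation_to_final_average(self, rng):
        """At the fixed point every model holds the op minimising its deviation."""
        models = self.make_models(rng)
        mixed = [_apply_symop(m, self.TWOFOLD, CELL) if i < 6 else m
                 for i, m in enumerate(models)]
        out, chosen = collapse_symmetry(mixed, [self.IDENT, self.TWOFOLD], CELL)
        avg = average_coordinates(out)

        def dev(m):
            pos = avg.positions_of(m.atom_keys)
            return np.linalg.norm(m.coords - avg.cbar[pos], axis=1).mean()

        for m in out:
            alt = _apply_symop(m, self.TWOFOLD, CELL)
            assert dev(m) <= dev(alt) + 1e-9

    def test_operators_must_include_identity(self, rng):
        models = self.make_models(rng, n=3)
        with pytest.raises(ValueError, match="identity"):
            collapse_symmetry(models, [self.TWOFOLD], CELL)

    def test_spacegroup_operator_generation(self):
        ops = operators_from_spacegroup("P 21 21 21")
        assert len(ops) == 4
        assert ops[0].is_identity
        for op in ops:
            assert abs(abs(np.linalg.det(op.rotation)) - 1.0) < 1e-12


class TestIndexOps:
    @pytest.mark.parametrize("triplet", ["h,k,l", "k,h,-l", "-h,-k,l", "l,h,k"])
    def test_parse_format_roundtrip(self, triplet):
        mat = parse_index_op(triplet)
        assert index_op_triplet(mat) == triplet

    def test_known_matrix(self):
        np.testing.assert_array_equal(
            parse_index_op("k,h,-l"),
            [[0, 1, 0], [1, 0, 0], [0, 0, -1]],
        )

    def test_non_bijective_rejected(self):
        with pytest.raises(ValueError):
            parse_index_op("h,h,l")
        with pytest.raises(ValueError):
            apply_index_op(
                ReflectionSet("d", [(1, 0, 0)], [1.0], CELL),
                np.array([[1, 0, 0], [1, 0, 0], [0, 0, 1]]),
            )

    def test_apply_remaps_indices(self):
        rs = ReflectionSet("d", [(1, 2, 3)], [1.0], CELL)
        out = apply_index_op(rs, parse_index_op("k,h,-l"))
        assert out.hkl.tolist() == [[2, 1, -3]]


class TestResolveIndexing:
    def consistent_sets(self, seed=3, n=10):
        res = generate_multidataset(
            FixtureSpec(n_clusters=1, sizes=[n], n_reflections=150, n_atoms=10,
                        cell_jitter=0.0, seed=seed)
        )
        return res.mds.reflection_sets

    def test_consistent_input_keeps_identity(self):
        sets = self.consistent_sets()
        resolved, report = resolve_indexing(sets, ["h,k,l", "k,h,-l"])
        assert set(report["chosen_op"]) == {"h,k,l"}
        for a, b in zip(sets, resolved):
            np.testing.assert_array_equal(a.hkl, b.hkl)

    def test_planted_flips_resolved_to_one_orientation(self):
        sets = self.consistent_sets(seed=5, n=20)
        flip = parse_index_op("k,h,-l")
        mixed = [apply_index_op(rs, flip) if i < 7 else rs for i, rs in enumerate(sets)]
        resolved, report = resolve_indexing(mixed, ["h,k,l", "k,h,-l"])
        # net orientation (planted flip composed with chosen op) is uniform
        planted = [flip if i < 7 else np.eye(3, dtype=np.int64) for i in range(20)]
        nets = {
            index_op_triplet(parse_index_op(ch) @ pl)
            for ch, pl in zip(report["chosen_op"], planted)
        }
        assert len(nets) == 1
        assert report["correlation_after"].min() > 0.99

    def test_identity_must_be_supplied(self):
        with pytest.raises(ValueError, match="identity"):
            resolve_indexing(self.consistent_sets(), ["k,h,-l"])


def test_end_to_end_planted_recovery_over_seeds():
    """Amplitude-perturbation fixtures at SNR 2 are recovered with high ARI."""
    from xtalcluster import MultiDatasetClusterer

    aris = []
    for seed in range(5):
        res = generate_multidataset(
            FixtureSpec(n_clusters=2, sizes=[10, 10], n_reflections=200,
                        n_atoms=20, seed=seed)
        )
        est = MultiDatasetClusterer(n_clusters=2, random_state=seed).fit(res.mds)
        truth = [res.labels[d] for d in res.mds.dataset_ids]
        aris.append(adjusted_rand_score(truth, est.labels_))
    assert np.mean(aris) >= 0.95
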