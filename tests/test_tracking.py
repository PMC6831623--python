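import numpy as np
import pytest

from eegdays.tracking import (
    CanonicalGroup,
    ICCluster,
    ICFeature,
    annotate_clusters,
    cluster_subject,
    commonality,
    ic_features,
    match_clusters_across_subjects,
    relocate_outliers,
    reproducibility,
    standardized_blocks,
)


def _component(session_id, comp, psd, m, dip, dipolarity=95.0):
    return {
        "session_id": session_id,
        "component": comp,
        "psd": np.asarray(psd, dtype=float),
        "map": np.asarray(m, dtype=float),
        "dip": np.asarray(dip, dtype=float),
        "dipolarity": dipolarity,
    }


def _random_components(rng, n=12, n_psd=50, n_ch=30):
    comps = []
    for i in range(n):
        comps.append(
            _component(
                f"D{i % 4}",
                i,
                rng.normal(size=n_psd),
                rng.normal(size=n_ch),
                rng.normal(size=3) * 20,
            )
        )
    return comps


class TestICFeatures:
    def test_identical_attributes_identical_vectors(self, rng):
        c1 = _component("D0", 0, rng.normal(size=50), rng.normal(size=30), [1.0, 2.0, 3.0])
        c2 = dict(c1, session_id="D1", component=1)
        others = _random_components(rng, n=4)
        feats, matrix = ic_features([c1, c2] + others)
        assert np.linalg.norm(matrix[0] - matrix[1]) == pytest.approx(0.0, abs=1e-12)

    def test_z_scoring(self, rng):
        comps = _random_components(rng, n=10)
        z = standardized_blocks(comps)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_dip_weight_dominates(self, rng):
        comps = _random_components(rng, n=8)
        _, m_big = ic_features(comps, weights=(1.0, 1.0, 1e6))
        dips = np.stack([standardize(np.stack([c["dip"] for c in comps]))])[0]
        from scipy.spatial.distance import pdist

        d_feat = pdist(m_big)
        d_dip = pdist(dips)
        assert np.array_equal(np.argsort(d_feat), np.argsort(d_dip))

    def test_missing_attribute_names_component(self, rng):
        comps = _random_components(rng, n=4)
        del comps[2]["psd"]
        with pytest.raises(ValueError, match="missing psd"):
            ic_features(comps)

    def test_map_polarity_aligned_unit_norm(self, rng):
        comps = _random_components(rng, n=5)
        feats, _ = ic_features(comps)
        for f in feats:
            assert np.linalg.norm(f.map) == pytest.approx(1.0, abs=1e-9)
            assert f.map[np.abs(f.map).argmax()] > 0


def standardize(b):
    sd = b.std(axis=0)
    return (b - b.mean(axis=0)) / np.where(sd > 0, sd, 1.0)


class TestClusterSubject:
    def _planted(self, rng, n_groups=3, per_group=8):
        comps, truth = [], []
        centres_psd = [rng.normal(size=50) * 3 for _ in range(n_groups)]
        centres_map = []
        for _ in range(n_groups):
            m = rng.normal(size=30) * 3
            i = np.abs(m).argmax()
            m[i] += np.sign(m[i]) * 10.0  # unambiguous polarity anchor
            centres_map.append(m)
        centres_dip = [rng.normal(size=3) * 40 for _ in range(n_groups)]
        i = 0
        for g in range(n_groups):
            for k in range(per_group):
                comps.append(
                    _component(
                        f"D{k}",
                        i,
                        centres_psd[g] + rng.normal(size=50) * 0.1,
                        centres_map[g] + rng.normal(size=30) * 0.1,
                        centres_dip[g] + rng.normal(size=3) * 1.0,
                    )
                )
                truth.append(g)
                i += 1
        return comps, np.array(truth)

    def test_planted_groups_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        comps, truth = self._planted(rng)
        feats, matrix = ic_features(comps)
        clusters = cluster_subject(feats, matrix, k=3, seed=0)
        labels = np.empty(len(feats), dtype=int)
        pos = {(f.session_id, f.component): i for i, f in enumerate(feats)}
        for ci, c in enumerate(clusters):
            for m in c.members:
                labels[pos[(m.session_id, m.component)]] = ci
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_singletons(self, rng):
        comps = _random_components(rng, n=6)
        feats, matrix = ic_features(comps)
        clusters = cluster_subject(feats, matrix, k=6, seed=0)
        assert len(clusters) == 6
        assert all(len(c.members) == 1 for c in clusters)

    def test_deterministic(self, rng):
        comps, _ = self._planted(rng)
        feats, matrix = ic_features(comps)
        c1 = cluster_subject(feats, matrix, k=3, seed=5)
        c2 = cluster_subject(feats, matrix, k=3, seed=5)
        m1 = [sorted((m.session_id, m.component) for m in c.members) for c in c1]
        m2 = [sorted((m.session_id, m.component) for m in c.members) for c in c2]
        assert m1 == m2

    def test_k_too_large_rejected(self, rng):
        comps = _random_components(rng, n=4)
        feats, matrix = ic_features(comps)
        with pytest.raises(ValueError):
            cluster_subject(feats, matrix, k=10, seed=0)

    def test_silhouette_scan_finds_planted_k(self):
        rng = np.random.default_rng(123)
        comps, truth = self._planted(rng, n_groups=6, per_group=6)
        feats, matrix = ic_features(comps)
        clusters = cluster_subject(feats, matrix, k=None, seed=0, k_range=(5, 10))
        assert len(clusters) == 6


def _simple_cluster(vectors, session_ids):
    members = [
        ICFeature(sid, i, psd=v[:50], map=_unitmap(v), dip=v[-3:])
        for i, (v, sid) in enumerate(zip(vectors, session_ids))
    ]
    mat = np.stack([np.concatenate([m.psd, m.map, m.dip]) for m in members])
    return ICCluster(
        members=members,
        centroid=mat.mean(axis=0),
        sessions_present=frozenset(session_ids),
    )


def _unitmap(v):
    m = v[50:80] if v.size >= 80 else np.ones(30)
    if np.linalg.norm(m) == 0:
        m = np.ones(30)
    m = m / np.linalg.norm(m)
    k = np.abs(m).argmax()
    return m if m[k] > 0 else -m


class TestRelocateOutliers:
    def _clusters(self, rng, spread=1.0):
        out = []
        for centre in (0.0, 100.0):
            vecs = [np.full(83, centre) + rng.normal(size=83) * spread for _ in range(8)]
            out.append(_simple_cluster(vecs, [f"D{i}" for i in range(8)]))
        return out

    def test_all_within_one_sd_unchanged(self):
        # controlled geometry: member-centroid distances spread well inside
        # one SD of each other, so nothing can exceed mean + 3 SD
        mags = [0.10, 0.11, 0.12, 0.13, 0.10, 0.11, 0.12, 0.13]
        clusters = []
        for centre in (0.0, 100.0):
            vecs = []
            for i in range(8):
                v = np.full(83, centre)
                v[i] += mags[i] if i % 2 == 0 else -mags[i]
                vecs.append(v)
            clusters.append(_simple_cluster(vecs, [f"D{i}" for i in range(8)]))
        new, outliers = relocate_outliers(clusters)
        assert outliers == []
        a = [sorted((m.session_id, m.component) for m in c.members) for c in clusters]
        b = [sorted((m.session_id, m.component) for m in c.members) for c in new]
        assert a == b

    def test_far_point_becomes_outlier(self, rng):
        clusters = self._clusters(rng)
        far = ICFeature("D9", 99, psd=np.full(50, 1e4), map=_unitmap(np.ones(83)), dip=np.full(3, 1e4))
        clusters[0].members.append(far)
        new, outliers = relocate_outliers(clusters)
        assert [(-1 if o is not far else 1) for o in outliers] == [1]
        total = sum(len(c.members) for c in new) + len(outliers)
        assert total == 17

    def test_relocation_to_nearer_cluster(self):
        # explicit geometry: clusters at 0 and 10 (1-D embedded), member of
        # cluster A sitting essentially on cluster B's centroid
        def vec(x):
            v = np.zeros(83)
            v[0] = x
            return v

        a_vecs = [vec(x) for x in (-0.3, -0.15, 0.0, 0.15, 0.3)]
        b_vecs = [vec(10 + x) for x in (-0.3, -0.15, 0.0, 0.15, 0.3)]
        stray = vec(10.05)  # ~0 SD from B centroid, huge distance from A
        a = _simple_cluster(a_vecs + [stray], ["D0", "D1", "D2", "D3", "D4", "D5"])
        b = _simple_cluster(b_vecs, ["D0", "D1", "D2", "D3", "D4"])
        new, outliers = relocate_outliers([a, b])
        assert outliers == []
        sizes = sorted(len(c.members) for c in new)
        assert sizes == [5, 6]
        big = max(new, key=lambda c: len(c.members))
        assert abs(big.centroid[0] - 10.0) < 1.0  # stray joined B

    def test_conservation(self, rng):
        clusters = self._clusters(rng, spread=5.0)
        before = sorted(
            (m.session_id, m.component) for c in clusters for m in c.members
        )
        new, outliers = relocate_outliers(clusters)
        after = sorted(
            [(m.session_id, m.component) for c in new for m in c.members]
            + [(m.session_id, m.component) for m in outliers]
        )
        assert before == after


class TestReproducibility:
    def test_6_of_8(self, rng):
        c = _simple_cluster([rng.normal(size=83) for _ in range(6)], [f"D{i}" for i in range(6)])
        assert reproducibility(c, 8) == 75.0

    def test_8_of_8(self, rng):
        c = _simple_cluster([rng.normal(size=83) for _ in range(8)], [f"D{i}" for i in range(8)])
        assert reproducibility(c, 8) == 100.0

    def test_two_members_one_session(self, rng):
        c = _simple_cluster([rng.normal(size=83), rng.normal(size=83)], ["D0", "D0"])
        assert reproducibility(c, 8) == 12.5

    def test_empty_cluster_rejected(self):
        c = ICCluster(members=[], centroid=np.zeros(3), sessions_present=frozenset())
        with pytest.raises(ValueError):
            reproducibility(c, 8)

    def test_brute_force_oracle(self, rng):
        # 1000 random clusters vs an independent distinct-session count
        for _ in range(1000):
            n_sessions = int(rng.integers(1, 12))
            n_members = int(rng.integers(1, 20))
            sids = [f"D{rng.integers(0, n_sessions)}" for _ in range(n_members)]
            members = [
                ICFeature(s, i, psd=np.zeros(50), map=_unitmap(np.ones(83)), dip=np.zeros(3))
                for i, s in enumerate(sids)
            ]
            c = ICCluster(members=members, centroid=np.zeros(3), sessions_present=frozenset(sids))
            brute = 100.0 * len({s for s in sids}) / n_sessions
            assert reproducibility(c, n_sessions) == pytest.approx(brute, abs=1e-12)


class TestCrossSubjectMatching:
    def _subject_clusters(self, rng, dips, maps=None, n_per=6):
        clusters = []
        for i, dip in enumerate(dips):
            m = maps[i] if maps is not None else rng.normal(size=30)
            vecs = []
            members = []
            for k in range(n_per):
                mm = m / np.linalg.norm(m)
                if mm[np.abs(mm).argmax()] < 0:
                    mm = -mm
                members.append(
                    ICFeature(f"D{k}", k, psd=rng.normal(size=50), map=mm, dip=np.asarray(dip, dtype=float))
                )
            mat = np.stack([np.concatenate([x.psd, x.map, x.dip]) for x in members])
            clusters.append(
                ICCluster(members=members, centroid=mat.mean(axis=0), sessions_present=frozenset(f"D{k}" for k in range(n_per)))
            )
        return clusters

    def test_identical_geometry_matches(self, rng):
        maps = [rng.normal(size=30) for _ in range(2)]
        dips = [[0.0, 50.0, 30.0], [0.0, -50.0, 30.0]]
        per_subject = {
            "S0": self._subject_clusters(rng, dips, maps),
            "S1": self._subject_clusters(rng, dips, maps),
            "S2": self._subject_clusters(rng, dips, maps),
        }
        groups = match_clusters_across_subjects(per_subject)
        assert len(groups) == 2
        assert all(len(g.clusters) == 3 for g in groups)

    def test_distant_centroids_unmatched(self, rng):
        m = rng.normal(size=30)
        per_subject = {
            "S0": self._subject_clusters(rng, [[0.0, 30.0, 30.0]], [m]),
            "S1": self._subject_clusters(rng, [[0.0, -30.0, 30.0]], [m]),  # 60 mm away
        }
        groups = match_clusters_across_subjects(per_subject)
        assert len(groups) == 2

    def test_sign_flipped_map_matches(self, rng):
        m = rng.normal(size=30)
        dip = [[10.0, 20.0, 30.0]]
        c0 = self._subject_clusters(rng, dip, [m])
        c1 = self._subject_clusters(rng, [[12.0, 21.0, 31.0]], [-m])
        groups = match_clusters_across_subjects({"S0": c0, "S1": c1})
        assert len(groups) == 1
        assert len(groups[0].clusters) == 2


class TestCommonality:
    def _groups(self, rng, days_per_subject):
        clusters = {}
        for s, n_days in days_per_subject.items():
            members = [
                ICFeature(f"D{k}", k, psd=np.zeros(50), map=_unitmap(np.ones(83)), dip=np.zeros(3))
                for k in range(n_days)
            ]
            clusters[s] = ICCluster(
                members=members,
                centroid=np.zeros(3),
                sessions_present=frozenset(f"D{k}" for k in range(n_days)),
            )
        return [CanonicalGroup(clusters=clusters, dip_centroid=np.zeros(3), map_centroid=np.ones(30))]

    def test_all_subjects_reproducible(self, rng):
        g = self._groups(rng, {f"S{i}": 7 for i in range(10)})
        rep = commonality(g, n_subjects=10, min_days=6, n_sessions=8)
        assert rep.rows[0]["commonality"] == 100.0

    def test_nine_of_ten(self, rng):
        days = {f"S{i}": 7 for i in range(9)}
        days["S9"] = 4
        rep = commonality(self._groups(rng, days), n_subjects=10, min_days=6, n_sessions=8)
        assert rep.rows[0]["commonality"] == 90.0

    def test_five_of_ten(self, rng):
        days = {f"S{i}": (8 if i < 5 else 3) for i in range(10)}
        rep = commonality(self._groups(rng, days), n_subjects=10, min_days=6, n_sessions=8)
        assert rep.rows[0]["commonality"] == 50.0

    def test_monotone_in_min_days(self, rng):
        days = {f"S{i}": int(1 + i * 0.8) for i in range(10)}
        groups = self._groups(rng, days)
        prev = 101.0
        for md in range(1, 9):
            val = commonality(groups, 10, min_days=md, n_sessions=8).rows[0]["commonality"]
            assert val <= prev
            prev = val

    def test_min_days_validation(self, rng):
        with pytest.raises(ValueError):
            commonality(self._groups(rng, {"S0": 3}), 1, min_days=9, n_sessions=8)


class TestAnnotate:
    def test_labels_and_reproducibility(self, rng):
        members = [
            ICFeature(f"D{k}", k, psd=np.zeros(50), map=_unitmap(np.ones(83)), dip=np.array([0.0, 55.0, 35.0]))
            for k in range(6)
        ]
        c = ICCluster(members=members, centroid=np.zeros(3), sessions_present=frozenset(f"D{k}" for k in range(6)))
        annotate_clusters([c], n_sessions=8)
        assert c.reproducibility == 75.0
        assert c.label == "frontal central"
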