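"""Ensemble superposition, RMSF, distance and interaction differencing."""

import numpy as np
import pytest

from glycoflex.ensembles import (
    Ensemble,
    InteractionRecord,
    RMSFProfile,
    compute_rmsf,
    delta_rmsf,
    distance_diff_network,
    interaction_diff,
    interaction_frequencies,
    read_ensemble,
    residue_min_distance_matrix,
    superpose,
    write_ensemble,
)
from glycoflex.synthetic import ScriptedMotif, gen_toy_ensemble

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   3       7.600   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  GLY A   1       0.000   1.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   1.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   3       7.600   1.000   0.000  1.00  0.00           C
ENDMDL
END
"""


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestReadWrite:
    def test_two_models_three_atoms(self):
        ens = read_ensemble(TWO_MODEL_PDB)
        assert ens.n_frames == 2 and ens.n_atoms == 3
        assert ens.coords[1, 0, 1] == pytest.approx(1.0)

    def test_single_model_rejected(self):
        single = TWO_MODEL_PDB.split("MODEL        2")[0] + "END\n"
        with pytest.raises(ValueError):
            read_ensemble(single)

    def test_roundtrip_stable(self):
        ens, _ = gen_toy_ensemble(seed=1, n_residues=5, n_frames=4)
        once = read_ensemble(write_ensemble(ens))
        np.testing.assert_allclose(once.coords, ens.coords, atol=1e-3)
        twice = read_ensemble(write_ensemble(once))
        np.testing.assert_array_equal(twice.coords, once.coords)
        np.testing.assert_array_equal(twice.residue_numbers, ens.residue_numbers)


class TestSuperpose:
    def test_rigid_transforms_exactly_removed(self):
        ens, _ = gen_toy_ensemble(seed=2, n_residues=8, n_frames=2, sigma=0.0)
        rng = np.random.default_rng(5)
        coords = ens.coords.copy()
        ref = coords[0]
        frames = [ref]
        for _ in range(4):
            rot = _random_rotation(rng)
            frames.append(ref @ rot + rng.normal(size=3))
        moved = Ensemble(np.array(frames), ens.atom_names, ens.elements,
                         ens.residue_numbers, ens.residue_names, ens.chains)
        sup = superpose(moved)
        for f in range(1, sup.n_frames):
            assert np.abs(sup.coords[f] - ref).max() < 1e-8

    def test_identity_on_reference(self):
        ens, _ = gen_toy_ensemble(seed=3, n_residues=6, n_frames=3)
        sup = superpose(ens, reference_frame=0)
        np.testing.assert_allclose(sup.coords[0], ens.coords[0], atol=1e-9)

    def test_never_increases_rmsd_to_reference(self):
        ens, _ = gen_toy_ensemble(seed=4, n_residues=8, n_frames=10, sigma=1.0)
        sup = superpose(ens)
        for f in range(ens.n_frames):
            before = np.sqrt(np.mean(np.sum((ens.coords[f] - ens.coords[0]) ** 2, axis=1)))
            after = np.sqrt(np.mean(np.sum((sup.coords[f] - sup.coords[0]) ** 2, axis=1)))
            assert after <= before + 1e-9

    def test_too_few_atoms_rejected(self):
        ens, _ = gen_toy_ensemble(seed=5, n_residues=4, n_frames=2)
        with pytest.raises(ValueError):
            superpose(ens, selection=np.array([True, False, False, False]))


class TestRMSF:
    def test_identical_frames_zero(self):
        ens, _ = gen_toy_ensemble(seed=6, n_residues=5, n_frames=4, sigma=0.0)
        prof = compute_rmsf(ens)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_two_frame_displacement(self):
        """One CA displaced by 2d across two frames: RMSF = d."""
        ens, _ = gen_toy_ensemble(seed=7, n_residues=4, n_frames=2, sigma=0.0)
        coords = ens.coords.copy()
        coords[1, 2, 2] += 2.0  # displace residue 3 by 2 A in z
        moved = Ensemble(coords, ens.atom_names, ens.elements,
                         ens.residue_numbers, ens.residue_names, ens.chains)
        prof = compute_rmsf(moved)
        assert prof.rmsf[2] == pytest.approx(1.0)
        assert prof.rmsf[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_generator_convention(self):
        """Per-axis sigma convention: expected RMSF = sigma*sqrt(3)."""
        sigma = np.array([0.0, 0.2, 0.4, 0.6, 0.3, 0.3, 0.3, 0.5])
        ens, truth = gen_toy_ensemble(seed=8, n_residues=8, n_frames=500, sigma=sigma)
        prof = compute_rmsf(ens)
        np.testing.assert_allclose(prof.rmsf, sigma * np.sqrt(3), atol=0.08)

    def test_invariant_under_global_rigid_transform(self):
        ens, _ = gen_toy_ensemble(seed=9, n_residues=6, n_frames=50, sigma=0.4)
        rng = np.random.default_rng(10)
        rot = _random_rotation(rng)
        moved = Ensemble(ens.coords @ rot + np.array([5.0, -3.0, 2.0]),
                         ens.atom_names, ens.elements, ens.residue_numbers,
                         ens.residue_names, ens.chains)
        np.testing.assert_allclose(compute_rmsf(moved).rmsf,
                                   compute_rmsf(ens).rmsf, atol=1e-8)


class TestDeltaRMSF:
    def _profile(self, values):
        ids = np.arange(1, len(values) + 1)
        return RMSFProfile(ids, np.asarray(values, float))

    def test_identical_profiles_no_significance(self):
        p = self._profile([0.5, 0.6, 0.7])
        d = delta_rmsf(p, p)
        assert d.significant_less_flexible == set()
        assert d.significant_more_flexible == set()

    def test_single_changed_residue(self):
        a = self._profile([0.5, 0.5, 1.5, 0.5])
        b = self._profile([0.5, 0.5, 0.5, 0.5])
        d = delta_rmsf(a, b)
        assert d.significant_less_flexible == {3}
        assert d.significant_more_flexible == set()

    def test_engineered_counts_match_published_pattern(self):
        """306 residues engineered so 126 are significantly less flexible
        and 20 more flexible — the fixture mirrors the published HRP counts."""
        rng = np.random.default_rng(11)
        n = 306
        base = rng.uniform(0.5, 1.0, n)
        delta = np.zeros(n)
        idx = rng.permutation(n)
        delta[idx[:126]] = rng.uniform(0.2, 1.0, 126)   # above 10% of max
        delta[idx[126:146]] = -rng.uniform(0.2, 1.0, 20)
        delta[idx[146:]] = rng.uniform(-0.05, 0.05, n - 146)  # below threshold
        ids = np.arange(1, n + 1)
        a = RMSFProfile(ids, base + np.clip(delta, 0, None))
        b = RMSFProfile(ids, base - np.clip(delta, None, 0))
        d = delta_rmsf(a, b, threshold_frac=0.10)
        assert len(d.significant_less_flexible) == 126
        assert len(d.significant_more_flexible) == 20
        assert not (d.significant_less_flexible & d.significant_more_flexible)

    def test_threshold_is_relative(self):
        a = self._profile([0.5, 0.5, 1.5, 0.4])
        b = self._profile([0.5, 0.5, 0.5, 0.5])
        d1 = delta_rmsf(a, b)
        a2 = RMSFProfile(a.residue_ids, a.rmsf * 7.0)
        b2 = RMSFProfile(b.residue_ids, b.rmsf * 7.0)
        d2 = delta_rmsf(a2, b2)
        assert d1.significant_less_flexible == d2.significant_less_flexible
        assert d1.significant_more_flexible == d2.significant_more_flexible

    def test_roster_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delta_rmsf(self._profile([0.5, 0.5]), self._profile([0.5, 0.5, 0.5]))


class TestDistanceMatrix:
    def test_static_ensemble_equals_single_frame(self):
        ens, _ = gen_toy_ensemble(seed=12, n_residues=5, n_frames=3, sigma=0.0)
        mat = residue_min_distance_matrix(ens)
        assert mat.loc[1, 2] == pytest.approx(3.8)
        assert mat.loc[1, 3] == pytest.approx(7.6)

    def test_mean_vs_min_aggregation(self):
        ens, _ = gen_toy_ensemble(seed=13, n_residues=2, n_frames=2, sigma=0.0)
        coords = ens.coords.copy()
        coords[0, 1, 0] = 4.0
        coords[1, 1, 0] = 6.0
        moved = Ensemble(coords, ens.atom_names, ens.elements,
                         ens.residue_numbers, ens.residue_names, ens.chains)
        assert residue_min_distance_matrix(moved).loc[1, 2] == pytest.approx(5.0)
        assert residue_min_distance_matrix(moved, mode="min").loc[1, 2] == pytest.approx(4.0)

    def test_matches_bruteforce(self):
        ens, _ = gen_toy_ensemble(seed=14, n_residues=10, n_frames=5, sigma=0.8)
        mat = residue_min_distance_matrix(ens).to_numpy()
        res_ids = ens.residue_ids
        oracle = np.zeros_like(mat)
        for f in range(ens.n_frames):
            for i, ri in enumerate(res_ids):
                for j, rj in enumerate(res_ids):
                    if i == j:
                        continue
                    ai = np.flatnonzero((ens.residue_numbers == ri) & (ens.elements != "H"))
                    aj = np.flatnonzero((ens.residue_numbers == rj) & (ens.elements != "H"))
                    dmin = min(
                        np.linalg.norm(ens.coords[f, a] - ens.coords[f, b])
                        for a in ai for b in aj
                    )
                    oracle[i, j] += dmin / ens.n_frames
        np.testing.assert_allclose(mat, oracle, atol=1e-9)
        np.testing.assert_allclose(mat, mat.T, atol=0)
        assert np.all(np.diag(mat) == 0)


class TestDistanceDiff:
    def _mat(self, values, ids):
        import pandas as pd

        return pd.DataFrame(values, index=ids, columns=ids)

    def test_identical_matrices_no_classified_edges(self):
        ens, _ = gen_toy_ensemble(seed=15, n_residues=6, n_frames=3, sigma=0.2)
        mat = residue_min_distance_matrix(ens)
        edges = distance_diff_network(mat, mat)
        assert all(e.delta_distance == 0 and e.closer_in == "none" for e in edges)

    def test_hand_enumerated_five_residue_case(self):
        ids = [1, 2, 3, 4, 8]
        a = np.full((5, 5), 20.0)
        b = np.full((5, 5), 20.0)
        np.fill_diagonal(a, 0)
        np.fill_diagonal(b, 0)
        # pair (1,2): within cutoff, closer in B by 0.5
        a[0, 1] = a[1, 0] = 5.0
        b[0, 1] = b[1, 0] = 4.5
        # pair (2,3): within cutoff, no significant change
        a[1, 2] = a[2, 1] = 4.0
        b[1, 2] = b[2, 1] = 4.1
        # pair (3,8): crosses the boundary, closer in A, long range
        a[2, 4] = a[4, 2] = 5.0
        b[2, 4] = b[4, 2] = 6.0
        # pair (1,4): outside cutoff in both
        a[0, 3] = a[3, 0] = 7.0
        b[0, 3] = b[3, 0] = 7.0
        edges = {(e.residue_i, e.residue_j): e
                 for e in distance_diff_network(self._mat(a, ids), self._mat(b, ids))}
        assert (1, 4) not in edges
        assert edges[(1, 2)].closer_in == "B"
        assert edges[(2, 3)].closer_in == "none"
        e38 = edges[(3, 8)]
        assert e38.closer_in == "A" and e38.long_range
        assert not edges[(1, 2)].long_range

    def test_scripted_contact_change_recovered(self):
        """Two static geometries differing by one 0.5 A contact shift."""
        base = np.zeros((8, 3))
        base[:, 0] = 3.8 * np.arange(8)
        shifted = base.copy()
        shifted[7, 0] -= 0.5  # residue 8 moves 0.5 A toward residue 7
        ens_a, _ = gen_toy_ensemble(seed=16, n_residues=8, n_frames=3,
                                    sigma=0.0, base_coords=base)
        ens_b, _ = gen_toy_ensemble(seed=16, n_residues=8, n_frames=3,
                                    sigma=0.0, base_coords=shifted)
        mats = [residue_min_distance_matrix(e) for e in (ens_a, ens_b)]
        edges = [e for e in distance_diff_network(mats[0], mats[1])
                 if e.closer_in != "none"]
        assert {(e.residue_i, e.residue_j) for e in edges} == {(7, 8)}
        assert edges[0].delta_distance == pytest.approx(0.5)


class TestInteractions:
    def test_scripted_frequencies(self):
        motifs = [ScriptedMotif("IONIC", 1.0), ScriptedMotif("HBOND", 0.25),
                  ScriptedMotif("PIPISTACK", 0.5), ScriptedMotif("VDW", 1.0)]
        ens, truth = gen_toy_ensemble(seed=17, n_residues=4, n_frames=40,
                                      sigma=0.05, motifs=motifs)
        recs = {(r.residue_i, r.residue_j, r.kind): r.frequency
                for r in interaction_frequencies(ens)}
        for m in truth["motifs"]:
            i, j = m["residues"]
            assert recs[(i, j, m["kind"])] == pytest.approx(m["fraction"])

    def test_pipistack_detected_in_exactly_scripted_frames(self):
        ens, truth = gen_toy_ensemble(seed=18, n_residues=4, n_frames=20,
                                      sigma=0.0, motifs=[ScriptedMotif("PIPISTACK", 0.3)])
        from glycoflex.ensembles import _frame_interactions

        m = truth["motifs"][0]
        i, j = m["residues"]
        on = set(m["on_frames"])
        for f in range(ens.n_frames):
            hits = _frame_interactions(ens, f, hbond_enabled=True)
            assert ((min(i, j), max(i, j), "PIPISTACK") in hits) == (f in on)

    def test_frequencies_bounded(self):
        ens, _ = gen_toy_ensemble(seed=19, n_residues=6, n_frames=10, sigma=1.0)
        assert all(0.0 <= r.frequency <= 1.0 for r in interaction_frequencies(ens))


class TestInteractionDiff:
    def _rec(self, i, j, kind, f):
        return InteractionRecord(i, j, kind, f)

    def test_self_difference_empty(self):
        recs = [self._rec(1, 5, "HBOND", 0.8), self._rec(2, 6, "VDW", 0.4)]
        assert interaction_diff(recs, recs) == []

    def test_simple_retention(self):
        a = [self._rec(1, 5, "HBOND", 0.9)]
        b = [self._rec(1, 5, "HBOND", 0.7)]
        out = interaction_diff(a, b)
        assert len(out) == 1
        assert out[0][5] == pytest.approx(0.2)

    def test_missing_record_counts_as_zero(self):
        a = [self._rec(1, 5, "IONIC", 0.5)]
        out = interaction_diff(a, [])
        assert out == [(1, 5, "IONIC", 0.5, 0.0, 0.5)]

    def test_matches_bruteforce_filter_and_conserves_counts(self):
        rng = np.random.default_rng(20)
        def randrecs(n):
            out = []
            for _ in range(n):
                i, j = sorted(rng.integers(1, 10, 2).tolist())
                if i == j:
                    continue
                kind = rng.choice(["HBOND", "VDW", "IONIC", "PIPISTACK"])
                out.append(self._rec(int(i), int(j), str(kind), float(rng.uniform())))
            # dedupe keys, keep last
            return list({(r.residue_i, r.residue_j, r.kind): r for r in out}.values())

        a, b = randrecs(30), randrecs(30)
        out = interaction_diff(a, b, threshold=0.10)
        fa = {(r.residue_i, r.residue_j, r.kind): r.frequency for r in a}
        fb = {(r.residue_i, r.residue_j, r.kind): r.frequency for r in b}
        keys = set(fa) | set(fb)
        oracle = {k for k in keys if abs(fa.get(k, 0) - fb.get(k, 0)) > 0.10}
        assert {tuple(e[:3]) for e in out} == oracle
        discarded = len(keys) - len(out)
        assert len(out) + discarded == len(keys)
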