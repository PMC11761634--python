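import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from foldcover._geom import random_rotation
from foldcover.motifsearch import (
    Motif,
    count_matches,
    excise_motif,
    kabsch_rmsd,
    motif_from_structure,
    read_motif,
    read_sigma_overrides,
    rmsd_threshold,
    search_motif,
)
from foldcover.structio import BackboneStructure, write_backbone
from foldcover.synth import TorsionSpec, build_backbone, perturb_backbone


def _segmented_motif(lengths, sigma_max=2.0, seed=0):
    rng = np.random.default_rng(seed)
    return Motif(
        name="m",
        segments=[rng.normal(size=(n, 3)) * 3 for n in lengths],
        sigma_max=sigma_max,
    )


def _threshold_oracle(lengths, sigma_max=2.0, corr_len=20.0):
    """Brute-force triple sum over the printed formula."""
    n_total = sum(lengths)
    acc = 0.0
    for n_k in lengths:
        for i in range(1, n_k):
            for j in range(i + 1, n_k + 1):
                acc += np.exp((i - j) / corr_len)
    return sigma_max * (1.0 - 2.0 / (n_total * (n_total - 1)) * acc)


def _partitions(n):
    """All ordered compositions of n into positive parts."""
    if n == 0:
        yield ()
        return
    for first in range(1, n + 1):
        for rest in _partitions(n - first):
            yield (first,) + rest


class TestRmsdThreshold:
    def test_two_residue_single_segment(self):
        m = _segmented_motif([2], sigma_max=2.0)
        assert rmsd_threshold(m) == pytest.approx(2.0 * (1 - np.exp(-0.05)), abs=1e-10)
        assert rmsd_threshold(m) == pytest.approx(0.09754, abs=5e-5)

    def test_single_residue_segments_give_sigma_max(self):
        m = _segmented_motif([1, 1], sigma_max=2.0)
        assert rmsd_threshold(m) == pytest.approx(2.0, abs=1e-12)

    def test_linear_in_sigma_max(self):
        a = rmsd_threshold(_segmented_motif([2], sigma_max=2.0))
        b = rmsd_threshold(_segmented_motif([2], sigma_max=1.0))
        assert b == pytest.approx(a / 2, abs=1e-12)
        assert b == pytest.approx(0.04877, abs=5e-5)

    def test_against_oracle_all_partitions_up_to_8(self):
        for n in range(2, 9):
            for parts in _partitions(n):
                m = _segmented_motif(list(parts))
                assert rmsd_threshold(m) == pytest.approx(
                    _threshold_oracle(list(parts)), abs=1e-12
                )

    def test_splitting_never_decreases_threshold(self):
        for n in range(2, 9):
            vals = {}
            for parts in _partitions(n):
                vals[parts] = rmsd_threshold(_segmented_motif(list(parts)))
            single = vals[(n,)]
            assert all(v >= single - 1e-12 for v in vals.values())
            # fully split = sigma_max is the maximum
            assert vals[tuple([1] * n)] == pytest.approx(2.0, abs=1e-12)


class TestKabschRmsd:
    def test_identity(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 3))
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transforms_give_zero(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(8, 3))
        for seed in range(20):
            r2 = np.random.default_rng(seed)
            b = a @ random_rotation(r2).T + r2.normal(size=3) * 10
            assert kabsch_rmsd(a, b) < 1e-8

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_numerical_minimization_oracle(self, seed):
        """Kabsch equals brute-force minimization over rotation angles."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(5, 3))
        b = a + rng.normal(scale=0.3, size=(5, 3))

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)

        def objective(rotvec):
            rot = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(np.mean(np.sum((ac @ rot.T - bc) ** 2, axis=1)))

        best = np.inf
        for trial in range(8):
            x0 = np.random.default_rng(trial).uniform(-np.pi, np.pi, 3)
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            best = min(best, res.fun)
        assert kabsch_rmsd(a, b) == pytest.approx(best, abs=1e-6)

    def test_displaced_square_corner(self):
        square = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float
        )
        displaced = square.copy()
        displaced[2, 0] += 0.4

        ac = square - square.mean(axis=0)
        bc = displaced - displaced.mean(axis=0)

        def objective(rotvec):
            rot = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(np.mean(np.sum((ac @ rot.T - bc) ** 2, axis=1)))

        best = min(
            minimize(
                objective,
                np.random.default_rng(t).uniform(-np.pi, np.pi, 3),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            ).fun
            for t in range(8)
        )
        assert kabsch_rmsd(square, displaced) == pytest.approx(best, abs=1e-6)

    def test_collinear_flagged(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.warns(UserWarning, match="collinear"):
            assert kabsch_rmsd(line, line) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSearchMotif:
    def test_planted_identity_match(self, mixed40):
        motif = excise_motif(mixed40, [(5, 11)], name="plant")
        hits = search_motif(motif, mixed40, threshold=0.5)
        assert hits
        assert hits[0].rmsd == pytest.approx(0.0, abs=1e-10)
        assert hits[0].placements[0] == (5, 11)

    def test_perturbed_recovery_and_rejection(self, mixed40):
        motif = excise_motif(mixed40, [(5, 11)], name="plant")
        mild = perturb_backbone(mixed40, 0.05, seed=1)
        hits = search_motif(motif, mild, threshold=0.5)
        assert hits and hits[0].rmsd < 0.5
        wrecked = perturb_backbone(mixed40, 5.0, seed=2)
        assert search_motif(motif, wrecked, threshold=0.5) == []

    def test_threshold_nesting(self, mixed40):
        motif = excise_motif(mixed40, [(4, 9), (20, 25)], name="two")
        noisy = perturb_backbone(mixed40, 0.15, seed=3)
        loose = search_motif(motif, noisy, threshold=1.0, max_matches=10_000)
        tight = search_motif(motif, noisy, threshold=0.3, max_matches=10_000)
        loose_keys = {tuple(h.placements) for h in loose}
        tight_keys = {tuple(h.placements) for h in tight}
        assert tight_keys <= loose_keys

    def test_order_flag(self, mixed40):
        # segments excised in swapped sequence order
        motif = excise_motif(mixed40, [(20, 25), (4, 9)], name="swapped")
        free = search_motif(motif, mixed40, threshold=0.1)
        strict = search_motif(motif, mixed40, threshold=0.1, ordered=True)
        assert any(h.rmsd < 1e-8 for h in free)
        assert all(
            h.placements[0][0] < h.placements[1][0] for h in strict
        )  # ordered hits respect query order; the swapped planting is absent
        assert not any(h.rmsd < 1e-8 for h in strict)

    def test_windows_respect_chain_breaks(self, mixed40):
        broken = BackboneStructure("br", mixed40.coords, chain_breaks=[22])
        motif = excise_motif(mixed40, [(20, 26)], name="w")
        hits = search_motif(motif, broken, threshold=1.0, max_matches=10_000)
        # the verbatim planting spans the break, so no hit may cross index 22
        for h in hits:
            for w0, w1 in h.placements:
                assert not (w0 <= 22 < w1 - 1)
        unbroken_hits = search_motif(motif, mixed40, threshold=1.0)
        assert any(h.rmsd < 1e-8 for h in unbroken_hits)

    def test_non_overlap(self, mixed40):
        motif = excise_motif(mixed40, [(5, 10), (5, 10)], name="dup")
        hits = search_motif(motif, mixed40, threshold=0.2)
        for h in hits:
            (a0, a1), (b0, b1) = h.placements
            assert a1 <= b0 or b1 <= a0


class TestCountMatches:
    def test_planted_counts(self, mixed40, helix20):
        motif = excise_motif(mixed40, [(5, 11)], name="plant")
        table = count_matches([motif], {"src": [mixed40], "other": [helix20]})
        by_set = dict(zip(table["set"], table["count"]))
        assert by_set["src"] >= 1

    def test_empty_set_zero(self):
        motif = _segmented_motif([3])
        table = count_matches([motif], {"empty": []})
        assert table["count"].tolist() == [0]

    def test_sigma_doubling_monotone(self, mixed40):
        structures = [perturb_backbone(mixed40, 0.3, seed=s) for s in range(6)]
        base = excise_motif(mixed40, [(5, 11)], name="m", sigma_max=1.0)
        double = excise_motif(mixed40, [(5, 11)], name="m", sigma_max=2.0)
        t1 = count_matches([base], {"s": structures})["count"].iloc[0]
        t2 = count_matches([double], {"s": structures})["count"].iloc[0]
        assert t2 >= t1

    def test_all_placements_flag(self, mixed40):
        motif = _segmented_motif([1, 1], sigma_max=2.0)  # trivially matches a lot
        one = count_matches([motif], {"s": [mixed40]}, one_per_structure=True)
        many = count_matches([motif], {"s": [mixed40]}, one_per_structure=False)
        assert one["count"].iloc[0] == 1
        assert many["count"].iloc[0] >= one["count"].iloc[0]


class TestMotifIO:
    def test_pdb_roundtrip_with_segments(self, tmp_path, mixed40):
        # write a discontinuous fragment: breaks delimit segments on re-read
        frag = BackboneStructure(
            "frag",
            np.concatenate([mixed40.coords[4:9], mixed40.coords[20:25]]),
            chain_breaks=[4],
        )
        p = tmp_path / "frag.pdb"
        write_backbone(frag, p)
        motif = read_motif(p)
        assert motif.segment_lengths == [5, 5]
        np.testing.assert_allclose(motif.segments[0], mixed40.ca[4:9], atol=1e-3)

    def test_sigma_override_table(self, tmp_path):
        p = tmp_path / "over.tsv"
        p.write_text("motif_name\tsigma_max\ncalcium_130482\t1.0\ncopper_034863\t1.5\n")
        over = read_sigma_overrides(p)
        assert over == {"calcium_130482": 1.0, "copper_034863": 1.5}
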