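import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from brainlattice import revinf, volgrid
from brainlattice.revinf import (
    DegenerateLabelError,
    StudyLabel,
    chi_square,
    contingency,
    fdr_bh,
    reverse_inference_map,
)

from conftest import random_activation


class TestContingency:
    def test_all_active_members(self):
        a, b, c, d = contingency([1, 1, 1], [True, True, True])
        assert (a, b, c, d) == (3, 0, 0, 0)

    def test_enumerated_mixed_case(self):
        assert contingency([1, 1, 0, 0], [1, 0, 1, 0]) == (1, 1, 1, 1)

    def test_matches_bruteforce_four_way_count(self):
        rng = np.random.default_rng(11)
        act = rng.integers(0, 2, 20).astype(bool)
        mem = rng.integers(0, 2, 20).astype(bool)
        a, b, c, d = contingency(act, mem)
        quad = [(x, m) for x, m in zip(act, mem)]
        assert a == quad.count((True, True))
        assert b == quad.count((True, False))
        assert c == quad.count((False, True))
        assert d == quad.count((False, False))
        assert a + b + c + d == 20


class TestChiSquare:
    def test_perfect_independence(self):
        assert chi_square((5, 5, 5, 5)) == (0.0, 1.0, 0)

    def test_worked_example(self):
        # expected cells are all 5; sum of (O-E)^2/E = 4 * 9/5 = 7.2
        stat, p, direction = chi_square((8, 2, 2, 8))
        assert stat == pytest.approx(7.2, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(7.2, 1))
        assert direction == 1

    def test_permutation_symmetry(self):
        s1, p1, d1 = chi_square((10, 0, 0, 10))
        s2, p2, d2 = chi_square((0, 10, 10, 0))
        assert s1 == s2 and p1 == p2
        assert (d1, d2) == (1, -1)

    def test_zero_marginal_signals_no_test(self):
        assert chi_square((3, 5, 0, 0)) == (0.0, 1.0, 0)
        assert chi_square((3, 0, 5, 0)) == (0.0, 1.0, 0)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_equals_scipy_oracle(self, counts):
        a, b, c, d = counts
        if min(a + b, c + d, a + c, b + d) == 0 or a + b + c + d == 0:
            return
        stat, p, _ = chi_square(counts)
        ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_oracle_equivalence_on_random_tables(self):
        rng = np.random.default_rng(42)
        tables = rng.integers(0, 50, size=(1000, 4))
        for t in tables:
            a, b, c, d = (int(x) for x in t)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            stat, _, _ = chi_square((a, b, c, d))
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert abs(stat - ref.statistic) <= 1e-10


class TestFdrBH:
    def test_hand_worked_pair(self):
        # 0.001 <= 0.05 * 1/2 passes; 0.9 fails
        assert fdr_bh([0.001, 0.9], q=0.05).tolist() == [True, False]

    def test_all_zero_kept_all_one_rejected(self):
        assert fdr_bh(np.zeros(5)).all()
        assert not fdr_bh(np.ones(5)).any()

    def test_empty_input(self):
        assert fdr_bh(np.array([])).size == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_hand_bh_procedure(self, pvals):
        q = 0.05
        keep = fdr_bh(pvals, q=q)
        # oracle: the textbook step-up procedure
        p = np.asarray(pvals)
        order = np.argsort(p)
        m = len(p)
        ks = [k for k in range(1, m + 1) if p[order[k - 1]] <= q * k / m]
        if ks:
            cutoff = p[order[max(ks) - 1]]
            expected = p <= cutoff
        else:
            expected = np.zeros(m, dtype=bool)
        assert np.array_equal(keep, expected)

    def test_survivors_nondecreasing_in_q(self):
        rng = np.random.default_rng(5)
        p = rng.random(200) ** 2
        counts = [fdr_bh(p, q).sum() for q in (0.01, 0.05, 0.1, 0.2, 0.5)]
        assert counts == sorted(counts)


class TestReverseInferenceMap:
    def test_degenerate_label_errors_with_name(self):
        rng = np.random.default_rng(0)
        am = random_activation(rng, 10, 30)
        label = StudyLabel("everything", np.ones(10, dtype=bool))
        with pytest.raises(DegenerateLabelError, match="everything"):
            reverse_inference_map(am, label)

    def test_constant_activity_gives_empty_map(self):
        rng = np.random.default_rng(1)
        values = np.ones((12, 20), dtype=np.uint8)
        am = volgrid.ActivationMatrix(
            studies=[f"S{i}" for i in range(12)], values=values
        )
        label = StudyLabel("coinflip", rng.integers(0, 2, 12).astype(bool))
        lm = reverse_inference_map(am, label)
        assert np.all(lm.z == 0)

    def test_significance_zeroing_biconditional(self):
        rng = np.random.default_rng(2)
        am = random_activation(rng, 30, 400)
        # plant association in the first voxels
        member = rng.integers(0, 2, 30).astype(bool)
        am.values[:, :40] = member[:, None]
        lm = reverse_inference_map(am, StudyLabel("planted", member), q=0.05)
        nonzero = lm.z != 0
        assert np.array_equal(nonzero, lm.p <= 0.05)
        assert np.all(lm.z[nonzero] > 0)
        assert np.isfinite(lm.z).all() and np.isfinite(lm.p).all()

    def test_planted_author_map_confined_to_focus(self, grid, demo_corpus, demo_maps):
        """A PI planted at a focus yields nonzero voxels only near it."""
        tables, manifest = demo_corpus
        _, _, author_maps = demo_maps
        lm = author_maps["PI_5"]  # no planted joint papers: single territory
        focus = manifest["foci"][manifest["pi_focus"]["PI_5"]]
        center = np.asarray(focus["center"])
        assert np.count_nonzero(lm.z) > 0
        hot = grid.voxel_centers[lm.z > 0]
        dists = np.linalg.norm(hot - center, axis=1)
        assert dists.max() <= 2 * focus["radius"] + 1e-9

    def test_signed_variant_keeps_negative_survivors(self):
        rng = np.random.default_rng(3)
        am = random_activation(rng, 40, 200)
        member = np.zeros(40, dtype=bool)
        member[:20] = True
        am.values[:, :20] = (~member[:, None]).astype(np.uint8)  # anti-associated
        signed = reverse_inference_map(am, StudyLabel("anti", member), signed=True)
        positive_only = reverse_inference_map(am, StudyLabel("anti", member))
        assert (signed.z < 0).any()
        assert not (positive_only.z < 0).any()
        assert np.all(positive_only.z[signed.z < 0] == 0)


class TestBatchMaps:
    def test_skips_degenerate_and_logs(self, caplog):
        rng = np.random.default_rng(4)
        am = random_activation(rng, 12, 30)
        labels = [
            StudyLabel(f"L{i}", rng.integers(0, 2, 12).astype(bool)) for i in range(3)
        ]
        labels = [
            lab
            if 0 < lab.n_member < 12
            else StudyLabel(lab.label_id, np.arange(12) < 6)
            for lab in labels
        ]
        labels.append(StudyLabel("degen", np.zeros(12, dtype=bool)))
        with caplog.at_level("WARNING"):
            maps = revinf.batch_maps(am, labels)
        assert set(maps) == {"L0", "L1", "L2"}
        assert any("degen" in r.message for r in caplog.records)

    def test_deterministic(self, demo_corpus, demo_maps):
        tables, _ = demo_corpus
        am, term_maps, _ = demo_maps
        again = revinf.batch_maps(am, revinf.term_labels(tables, am.studies))
        assert set(again) == set(term_maps)
        for k, lm in term_maps.items():
            assert np.array_equal(again[k].z, lm.z)
            assert np.array_equal(again[k].p, lm.p)

    def test_far_foci_terms_have_disjoint_support(self, demo_corpus, demo_maps):
        """Terms planted in different cohorts never light the same voxels."""
        tables, manifest = demo_corpus
        _, term_maps, _ = demo_maps
        cohort_of = {
            t: {f[1] for f in fs} for t, fs in manifest["term_foci"].items()
        }
        for t1, lm1 in term_maps.items():
            for t2, lm2 in term_maps.items():
                if cohort_of[t1] != cohort_of[t2]:
                    assert ((lm1.z > 0) & (lm2.z > 0)).sum() == 0


def test_write_maps_index(demo_maps, grid, tmp_path):
    _, term_maps, _ = demo_maps
    index = revinf.write_maps(term_maps, grid, tmp_path, kind="term")
    assert len(index) == len(term_maps)
    assert set(index["label_id"]) == set(term_maps)
    for _, row in index.iterrows():
        data = volgrid.read_volume(tmp_path / row["file"], grid)
        assert np.count_nonzero(data) == row["n_nonzero_voxels"]
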