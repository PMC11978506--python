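import numpy as np
import pytest

from contactdiff import (
    ContactMap,
    compare_tracks,
    directionality_track,
    distance_enrichment_track,
    eigenvector_track,
    insulation_track,
)
from contactdiff.core import DegenerateInputError
from contactdiff.tracks import Track

from conftest import symmetric_map


def two_block_map(n=24, split=12, high=1.0):
    """Two dense blocks along the diagonal with zero inter-block contact."""
    v = np.zeros((n, n))
    v[:split, :split] = high
    v[split:, split:] = high
    return ContactMap(values=v)


class TestInsulation:
    def test_constant_map_constant_track(self):
        t = insulation_track(ContactMap(values=np.full((30, 30), 0.7)), window=10)
        assert np.all(t.values[t.defined] == pytest.approx(0.7))

    def test_edge_arithmetic(self):
        t = insulation_track(ContactMap(values=np.zeros((25, 25))), window=10)
        assert list(np.where(t.defined)[0]) == [10, 11, 12, 13, 14]

    def test_minimum_at_boundary(self):
        t = insulation_track(two_block_map(), window=5)
        defined_vals = np.where(t.defined, t.values, np.inf)
        # the boundary bin sits on the minimum plateau of the track
        assert t.values[12] == defined_vals.min()
        assert defined_vals[9] > defined_vals.min() < defined_vals[15]

    def test_too_small_map_rejected(self):
        with pytest.raises(DegenerateInputError):
            insulation_track(ContactMap(values=np.zeros((10, 10))), window=10)

    def test_fully_masked_block_undefined(self, rng):
        m = symmetric_map(rng, n=25)
        m.mask[:] = True
        t = insulation_track(m, window=10)
        assert not t.defined.any()


class TestDirectionality:
    def test_symmetric_surroundings_zero(self, rng):
        # transposition-symmetric neighborhoods give A = B at every bin
        v = np.zeros((30, 30))
        for d in range(1, 6):
            idx = np.arange(30 - d)
            v[idx, idx + d] = v[idx + d, idx] = 1.0 / d
        t = directionality_track(ContactMap(values=v), replace_ends=False)
        interior = slice(5, 25)
        assert np.all(t.values[interior] == 0)

    def test_direct_formula(self):
        # bin 10: A (upstream sum) = 1, B (downstream sum) = 3 -> E = 2,
        # value = +((1-2)^2/2 + (3-2)^2/2) = 1.0
        v = np.zeros((30, 30))
        v[10, 7] = v[7, 10] = 1.0
        v[10, 13] = v[13, 10] = 3.0
        t = directionality_track(ContactMap(values=v), replace_ends=False)
        assert t.values[10] == pytest.approx(1.0)

    def test_replace_ends_buffer(self, rng):
        m = symmetric_map(rng, n=448)
        t = directionality_track(m, replace_ends=True, buffer=50)
        assert np.all(t.values[:50] == 0)
        assert np.all(t.values[398:] == 0)
        assert np.any(t.values[50:398] != 0)

    def test_subbin_window_rejected(self, rng):
        with pytest.raises(ValueError):
            directionality_track(symmetric_map(rng, n=30), window_resolution=500)


class TestEigenvector:
    def test_two_block_sign_structure(self):
        blocks = (np.arange(20) < 10).astype(int)
        v = np.where(np.add.outer(blocks, blocks) % 2, -0.5, 0.5).astype(float)
        t = eigenvector_track(ContactMap(values=v))
        assert t.defined.all()
        left, right = t.values[:10], t.values[10:]
        assert np.all(np.sign(left) == np.sign(left[0]))
        assert np.all(np.sign(right) == np.sign(right[0]))
        assert np.sign(left[0]) != np.sign(right[0])

    def test_shift_invariance(self, rng):
        m = symmetric_map(rng, n=15)
        shifted = m.copy()
        shifted.values = shifted.values + 3.0
        assert eigenvector_track(m).values == pytest.approx(eigenvector_track(shifted).values)

    def test_sign_flip_same_comparison_score(self, rng):
        t1 = eigenvector_track(symmetric_map(rng, n=15))
        t2 = Track(values=-t1.values, defined=t1.defined, kind="eigenvector",
                   bin_size=t1.bin_size)
        rec = compare_tracks(t1, t2, stat="mse")
        assert rec.aligned == pytest.approx(0.0, abs=1e-12)

    def test_constant_map_all_undefined(self):
        t = eigenvector_track(ContactMap(values=np.ones((10, 10))))
        assert not t.defined.any()


class TestDistanceEnrichment:
    def test_constant_map(self):
        t = distance_enrichment_track(ContactMap(values=np.full((6, 6), 0.3)))
        assert t.defined.all()
        assert np.all(t.values == pytest.approx(0.3))

    def test_per_diagonal_means(self):
        v = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
        t = distance_enrichment_track(ContactMap(values=v))
        assert t.values == pytest.approx([0.0, 1.0, 2.0])

    def test_empty_stratum_undefined(self, rng):
        m = symmetric_map(rng, n=6)
        m.mask[0, 5] = m.mask[5, 0] = True
        t = distance_enrichment_track(m)
        assert not t.defined[5]
        assert t.defined[:5].all()


class TestCompareTracks:
    def test_identical_tracks_zero(self, rng):
        m = symmetric_map(rng, n=25)
        tracks = [insulation_track(m), directionality_track(m, buffer=5),
                  eigenvector_track(m), distance_enrichment_track(m)]
        for t in tracks:
            for stat in ["corr", "mse"]:
                rec = compare_tracks(t, t, stat=stat)
                assert rec.aligned == pytest.approx(0.0, abs=1e-12), (t.kind, stat)

    def test_mse_direct_arithmetic(self):
        t1 = Track(values=np.array([1.0, 2, 3]), defined=np.ones(3, bool),
                   kind="decay", bin_size=2048)
        t2 = Track(values=np.array([1.0, 2, 5]), defined=np.ones(3, bool),
                   kind="decay", bin_size=2048)
        assert compare_tracks(t1, t2, stat="mse").aligned == pytest.approx(4 / 3)

    def test_kind_mismatch_rejected(self):
        t1 = Track(values=np.zeros(3), defined=np.ones(3, bool), kind="decay", bin_size=1)
        t2 = Track(values=np.zeros(3), defined=np.ones(3, bool), kind="insulation", bin_size=1)
        with pytest.raises(TypeError):
            compare_tracks(t1, t2)

    def test_too_few_joint_positions_undefined(self):
        t1 = Track(values=np.arange(5.0), defined=np.array([1, 1, 0, 0, 0], bool),
                   kind="decay", bin_size=1)
        t2 = Track(values=np.arange(5.0), defined=np.ones(5, bool), kind="decay", bin_size=1)
        assert compare_tracks(t1, t2, stat="corr").status == "undefined"


@pytest.mark.parametrize("fn", [insulation_track, directionality_track,
                                eigenvector_track, distance_enrichment_track])
def test_transposition_invariance(rng, fn):
    m = symmetric_map(rng, n=25)
    mt = ContactMap(values=m.values.T.copy(), bin_size=m.bin_size)
    a, b = fn(m), fn(mt)
    assert np.array_equal(a.defined, b.defined)
    assert a.values[a.defined] == pytest.approx(b.values[b.defined])
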