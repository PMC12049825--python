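import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import vocseq
from vocseq.space import ACTIVATION_PLANE, PlaneSpec, direction_sector
from conftest import make_sequence


class TestChangeVectors:
    def test_percent_change_arithmetic(self):
        seq = make_sequence(duration=[0.2, 0.5], maxfreq=[800, 800])
        (v,) = vocseq.change_vectors(seq, ACTIVATION_PLANE, mode="percent")
        assert v.dx == pytest.approx(150.0)
        assert v.dy == pytest.approx(0.0)

    def test_zero_displacement_has_no_angle(self):
        seq = make_sequence(duration=[1.0, 1.0], maxfreq=[800, 800])
        (v,) = vocseq.change_vectors(seq, ACTIVATION_PLANE, mode="absolute")
        assert v.distance == 0
        assert math.isnan(v.angle)

    def test_percent_change_signed_with_abs_denominator(self):
        # slope moving -2 -> +2 is a +200% change of magnitude 2
        seq = make_sequence(freqslope=[-2.0, 2.0], acentropy=[2.0, 2.0])
        (v,) = vocseq.change_vectors(seq, vocseq.MODULATION_PLANE, mode="percent")
        assert v.dx == pytest.approx(200.0)

    def test_zero_current_value_flags_vector(self):
        seq = make_sequence(freqslope=[0.0, 2.0], acentropy=[2.0, 2.5])
        (v,) = vocseq.change_vectors(seq, vocseq.MODULATION_PLANE, mode="percent")
        assert not v.defined
        summary = vocseq.slice_summary([v])
        assert summary.empty

    def test_vector_count_is_n_minus_1(self, rng):
        seq = make_sequence(maxfreq=rng.uniform(500, 1500, 17))
        assert len(vocseq.change_vectors(seq, ACTIVATION_PLANE)) == 16

    def test_requires_two_calls(self):
        with pytest.raises(ValueError):
            vocseq.change_vectors(make_sequence(maxfreq=[800]), ACTIVATION_PLANE)


class TestDirectionMap:
    def test_eastward_transition_counts_once(self):
        plane = PlaneSpec("duration_s", "maxfreq_hz", x_bins=2, y_bins=2,
                          x_range=(0, 1), y_range=(0, 1000))
        seq = make_sequence(duration=[0.2, 0.8], maxfreq=[200, 200])
        dmap = vocseq.grid_direction_map(seq, plane)
        row = dmap.table.iloc[0]
        assert (row.cell_x, row.cell_y, row.direction, row["count"]) == (0, 0, "E", 1)

    def test_identical_transitions_accumulate(self):
        plane = PlaneSpec("duration_s", "maxfreq_hz", x_bins=2, y_bins=2,
                          x_range=(0, 1), y_range=(0, 1000))
        seq = make_sequence(duration=[0.2, 0.8, 0.2, 0.8], maxfreq=[200] * 4)
        dmap = vocseq.grid_direction_map(seq, plane)
        east = dmap.table.query("direction == 'E'")
        assert east["count"].item() == 2

    def test_toy_path_emits_n_minus_1_arrows(self):
        # brute-force oracle: 5 calls -> 4 consecutive pairs, whatever cells
        seq = make_sequence(duration=[0.1, 0.5, 0.9, 0.5, 0.1],
                            maxfreq=[100, 500, 900, 500, 100])
        for summary in ("direction", "distance"):
            dmap = vocseq.grid_direction_map(seq, ACTIVATION_PLANE, summary=summary)
            assert dmap.total_count == 4

    def test_conservation_on_random_sequences(self, rng):
        for n in (2, 5, 23, 61):
            seq = make_sequence(duration=rng.uniform(0.1, 2, n),
                                maxfreq=rng.uniform(300, 1700, n))
            dmap = vocseq.grid_direction_map(seq, ACTIVATION_PLANE)
            assert dmap.total_count == n - 1

    def test_out_of_range_errors_when_requested(self):
        plane = PlaneSpec("duration_s", "maxfreq_hz", x_range=(0, 1),
                          y_range=(0, 500), clip="error")
        seq = make_sequence(duration=[0.5, 0.6], maxfreq=[200, 900])
        with pytest.raises(ValueError, match="range"):
            vocseq.grid_direction_map(seq, plane)


class TestSliceSummary:
    @staticmethod
    def _vectors(angles, distances):
        return [
            vocseq.ChangeVector(i, i + 1,
                                d * math.cos(math.radians(a)),
                                d * math.sin(math.radians(a)),
                                d, a)
            for i, (a, d) in enumerate(zip(angles, distances))
        ]

    def test_uniform_distances_collapse(self):
        vecs = self._vectors([10] * 5, [1] * 5)
        out = vocseq.slice_summary(vecs, 8)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["count"] == 5
        assert row.median_distance == row.p2_5 == row.p97_5 == 1

    def test_linear_interpolation_quantiles(self):
        # closed form for 1..100: median 50.5, 2.5% at 1 + 0.025*99 = 3.475
        vecs = self._vectors([10] * 100, list(range(1, 101)))
        row = vocseq.slice_summary(vecs, 8).iloc[0]
        assert row.median_distance == pytest.approx(50.5)
        assert row.p2_5 == pytest.approx(3.475)
        assert row.p97_5 == pytest.approx(97.525)

    def test_empty_slices_absent(self):
        vecs = self._vectors([10, 100], [1, 2])
        out = vocseq.slice_summary(vecs, 8)
        assert set(out["slice"]) == {0, 2}


def test_direction_sector_boundaries():
    assert direction_sector(0) == "E"
    assert direction_sector(22.4) == "E"
    assert direction_sector(22.5) == "NE"
    assert direction_sector(337.5) == "E"
    assert direction_sector(180) == "W"


@given(
    st.lists(st.floats(0.05, 3), min_size=3, max_size=10),
    st.lists(st.floats(100, 2000), min_size=3, max_size=10),
    st.floats(0.1, 50),
)
def test_percent_vectors_invariant_to_positive_rescaling(dur, mf, scale):
    n = min(len(dur), len(mf))
    base = make_sequence(duration=dur[:n], maxfreq=mf[:n])
    scaled = make_sequence(duration=np.array(dur[:n]) * scale, maxfreq=mf[:n])
    va = vocseq.change_vectors(base, ACTIVATION_PLANE, mode="percent")
    vb = vocseq.change_vectors(scaled, ACTIVATION_PLANE, mode="percent")
    for a, b in zip(va, vb):
        assert a.dx == pytest.approx(b.dx, rel=1e-9)
        assert a.dy == pytest.approx(b.dy, rel=1e-9)


def test_percent_and_absolute_agree_on_sign_quadrant(rng):
    # with positive current values the sign pattern (hence quadrant) of the
    # displacement matches between modes
    seq = make_sequence(duration=rng.uniform(0.1, 2, 30),
                        maxfreq=rng.uniform(300, 1700, 30))
    va = vocseq.change_vectors(seq, ACTIVATION_PLANE, mode="absolute")
    vp = vocseq.change_vectors(seq, ACTIVATION_PLANE, mode="percent")
    for a, p in zip(va, vp):
        assert np.sign(a.dx) == np.sign(p.dx)
        assert np.sign(a.dy) == np.sign(p.dy)


def test_pooling_levels_partition_vectors(rng):
    seqs = [
        make_sequence(maxfreq=rng.uniform(500, 1500, 10), subject=s, session=ss)
        for s in ("A", "B")
        for ss in ("s1", "s2")
    ]
    total = sum(len(s) - 1 for s in seqs)
    for by, n_groups in (("all", 1), ("subject", 2), ("session", 4)):
        groups = vocseq.pooled_change_vectors(seqs, ACTIVATION_PLANE, by=by)
        assert len(groups) == n_groups
        assert sum(len(v) for v in groups.values()) == total
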