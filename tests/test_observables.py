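"""Observables on scripted fixtures: histogram normalization, episode
run-length encoding, occupancy conditioning, shuttle counting,
residence fractions."""

import numpy as np
import pytest

from npcbd.observables import (BondEpisode, EmptyTrackError,
                               UndefinedObservableError, bond_lifetimes,
                               channel_residence_fraction, occupancy,
                               radial_probability, shuttle_count)


class _Frame:
    y_chan_top = 0.0
    y_chan_mid = -15.0
    y_chan_bot = -30.0
    r_min = 13.0


def test_uniform_radial_track_gives_flat_histogram():
    rng = np.random.default_rng(0)
    n = 200_000
    track = np.stack([rng.uniform(0, 10, n), rng.uniform(-30, 0, n)], axis=1)
    h = radial_probability(track, _Frame(), bin_nm=1.0)
    assert h.probability.sum() == pytest.approx(1.0)
    assert h.n_samples == n
    # each of the 10 bins ~0.1 within multinomial error
    assert np.allclose(h.probability, 0.1, atol=0.005)


def test_constant_radius_track_single_bin():
    track = np.tile([5.5, -10.0], (100, 1))
    h = radial_probability(track, _Frame())
    occupied = h.probability > 0
    assert occupied.sum() == 1
    assert h.probability.max() == pytest.approx(1.0)


def test_out_of_channel_samples_are_excluded():
    track = np.array([[3.0, 10.0], [3.0, -40.0]])  # both outside channel
    with pytest.raises(EmptyTrackError):
        radial_probability(track, _Frame())


def test_histogram_conserves_sample_count():
    rng = np.random.default_rng(1)
    inside = np.stack([rng.uniform(0, 8, 500), rng.uniform(-29, -1, 500)], axis=1)
    outside = np.stack([rng.uniform(0, 8, 200), np.full(200, 5.0)], axis=1)
    h = radial_probability(np.vstack([inside, outside]), _Frame())
    assert h.n_samples == 500


def test_bond_lifetime_run_length_encoding():
    """Episode count equals the number of contact on-runs; lifetimes are
    steps x dt; a single-step contact has the minimum lifetime."""
    dt = 0.01  # ns per step
    pattern = [[(0, 5)], [(0, 5)], [], [(0, 5)], [], [], [(1, 7)]]
    episodes, summary = bond_lifetimes(pattern, dt)
    assert summary["n"] == 3
    lives_05 = sorted(e.lifetime for e in episodes if (e.spot, e.motif) == (0, 5))
    lives_17 = [e.lifetime for e in episodes if (e.spot, e.motif) == (1, 7)]
    assert lives_05 == [pytest.approx(dt), pytest.approx(2 * dt)]
    assert lives_17 == [pytest.approx(dt)]
    assert summary["min"] == pytest.approx(dt)  # one step = 0.01 ns


def test_bond_episodes_partition_contact_steps():
    """Episodes are disjoint and cover exactly the in-contact steps."""
    rng = np.random.default_rng(3)
    contact = rng.random(300) < 0.4
    steps = [[(0, 0)] if c else [] for c in contact]
    episodes, summary = bond_lifetimes(steps, 1.0)
    covered = np.zeros(300, bool)
    for e in episodes:
        sl = slice(int(e.start), int(e.end))
        assert not covered[sl].any()  # disjoint
        covered[sl] = True
    assert np.array_equal(covered, contact)
    assert sum(e.lifetime for e in episodes) == contact.sum()


def test_open_episode_closed_at_track_end():
    episodes, summary = bond_lifetimes([[(2, 9)], [(2, 9)]], 0.5)
    assert summary["n"] == 1
    assert episodes[0].lifetime == pytest.approx(1.0)


def test_occupancy_conditional_on_engagement():
    """Engaged-step conditioning: alternating 8-spot/idle steps average
    to 8, not 4."""
    eight = [(s, s) for s in range(8)]
    steps = [eight, [], eight, [], eight]
    assert occupancy(steps, n_spots=8) == pytest.approx(8.0)
    assert occupancy([eight] * 5, n_spots=8) == pytest.approx(8.0)


def test_occupancy_counts_spots_not_bonds():
    steps = [[(0, 1), (0, 2), (0, 3), (5, 9)]]  # one spot, many motifs
    assert occupancy(steps, n_spots=8) == pytest.approx(2.0)


def test_occupancy_undefined_without_engagement():
    with pytest.raises(UndefinedObservableError):
        occupancy([[], [], []])


def test_occupancy_bounded_by_spot_count():
    with pytest.raises(ValueError):
        occupancy([[(s, 0) for s in range(9)]], n_spots=8)


def test_monotone_track_has_zero_shuttles():
    y = np.linspace(10, -60, 500)
    assert shuttle_count(y, entry_plane=0.0, mid_plane=-15.0) == 0


def test_single_round_trip_counted_once():
    """Entry -> mid -> back past entry -> final passage: one shuttle."""
    y = np.concatenate([np.linspace(5, -16, 50), np.linspace(-16, 2, 50),
                        np.linspace(2, -60, 80)])
    assert shuttle_count(y, 0.0, -15.0) == 1


def test_double_round_trip_counted_twice():
    seg = np.concatenate([np.linspace(5, -16, 30), np.linspace(-16, 2, 30)])
    y = np.concatenate([seg, seg, np.linspace(2, -60, 50)])
    assert shuttle_count(y, 0.0, -15.0) == 2


def test_half_excursions_not_counted():
    """Dips that do not reach mid-channel, and mid-reaches that do not
    return past the entry, are not round trips."""
    y = np.concatenate([np.linspace(5, -10, 30), np.linspace(-10, 3, 30),
                        np.linspace(3, -60, 40)])
    assert shuttle_count(y, 0.0, -15.0) == 0


def test_shuttle_plane_ordering_validated():
    with pytest.raises(ValueError):
        shuttle_count(np.zeros(3), -15.0, 0.0)


def _record(times, ys, t_start, t_end, outcome="completed"):
    from npcbd.cargo import TransportRecord
    track = np.stack([np.zeros_like(ys), ys], axis=1)
    return TransportRecord(
        cargo=None, dt=1.0, sample_stride=1, steps=len(times),
        times=np.asarray(times, float), track=track,
        engaged_spots=np.zeros(len(times), np.int64),
        t_start=t_start, t_end=t_end, episode_steps=np.zeros(0, np.int64),
        contact_acc=np.zeros(8, np.int64), max_wlc_fraction=0.0,
        outcome=outcome, frame=_Frame())


def test_channel_residence_whole_passage_inside():
    times = np.arange(100, dtype=float)
    ys = np.full(100, -10.0)
    rec = _record(times, ys, t_start=0.0, t_end=99.0)
    assert channel_residence_fraction(rec) == pytest.approx(1.0)


def test_channel_residence_teleport_is_near_zero():
    """Almost the whole passage spent outside the channel."""
    times = np.arange(100, dtype=float)
    ys = np.concatenate([np.full(50, 10.0), np.full(50, -40.0)])
    rec = _record(times, ys, t_start=0.0, t_end=99.0)
    assert channel_residence_fraction(rec) == 0.0


def test_channel_residence_respects_fpt_window():
    times = np.arange(100, dtype=float)
    ys = np.concatenate([np.full(20, 5.0), np.full(60, -10.0),
                         np.full(20, -40.0)])
    rec = _record(times, ys, t_start=20.0, t_end=79.0)
    assert channel_residence_fraction(rec) == pytest.approx(1.0)


def test_channel_residence_undefined_for_incomplete():
    rec = _record(np.arange(5.0), np.zeros(5), None, None, outcome="timed_out")
    with pytest.raises(UndefinedObservableError):
        channel_residence_fraction(rec)
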