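"""Per-run and batch transport statistics.

All observables are pure functions of recorded trajectories and contact
sets, so they can be recomputed offline from saved runs.  The kap-FG
"bond" criterion is geometric: a binding spot and an FG motif are in
contact while their distance is below a threshold of the order of the
interaction well width (default 3 nm = 2 x the kap-FG characteristic
length).  The 10 nm force cutoff is deliberately not used as the bond
criterion: it would declare near-permanent bonds and suppress the
transient-bond statistics this model is built to expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class EmptyTrackError(ValueError):
    """No usable samples for the requested observable."""


class UndefinedObservableError(ValueError):
    """The observable is undefined for this record (e.g. inert cargo)."""


@dataclass
class RadialHistogram:
    """Normalized radial probability distribution with a Gaussian fit."""

    bin_edges: np.ndarray  # nm
    probability: np.ndarray  # sums to 1
    peak: float  # nm, fitted Gaussian center
    sd: float  # nm, fitted Gaussian width
    n_samples: int


@dataclass
class BondEpisode:
    """A maximal run of consecutive in-contact steps for one
    (spot, motif) pair."""

    spot: int
    motif: int
    start: float
    end: float
    lifetime: float


def radial_probability(track: np.ndarray, frame, bin_nm: float = 1.0
                       ) -> RadialHistogram:
    """Radial probability distribution of the cargo inside the channel.

    ``track`` is an (n, 2) array of cargo (x, y); samples are restricted
    to the channel region (y between the nuclear and cytoplasmic rings)
    and the radial coordinate is the absolute transverse coordinate
    measured from the pore axis.
    """
    track = np.asarray(track, float).reshape(-1, 2)
    mask = (track[:, 1] <= frame.y_chan_top) & (track[:, 1] >= frame.y_chan_bot)
    r = np.abs(track[mask, 0])
    if len(r) == 0:
        raise EmptyTrackError("no in-channel samples")
    edges = np.arange(0.0, np.ceil(r.max() / bin_nm) * bin_nm + bin_nm, bin_nm)
    if len(edges) < 2:
        edges = np.array([0.0, bin_nm])
    counts, edges = np.histogram(r, bins=edges)
    prob = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak, sd = _gaussian_fit(centers, prob, r)
    return RadialHistogram(bin_edges=edges, probability=prob, peak=peak,
                           sd=sd, n_samples=len(r))


def _gaussian_fit(centers, prob, samples):
    """Gaussian peak +- SD of a histogram; moment fallback if the
    least-squares fit fails."""
    import warnings

    from scipy.optimize import curve_fit

    mu0, sd0 = float(np.mean(samples)), float(np.std(samples) + 1e-9)
    if len(centers) < 4:
        return mu0, sd0
    def gauss(x, a, mu, sd):
        return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(gauss, centers, prob,
                                p0=[prob.max(), mu0, sd0], maxfev=5000)
        return float(popt[1]), float(abs(popt[2]))
    except Exception:
        return mu0, sd0


def bond_lifetimes(contacts_per_step, dt: float):
    """Run-length encode per-step contact sets into bond episodes.

    ``contacts_per_step`` is a sequence (one entry per step) of
    iterables of (spot, motif) pairs in contact during that step; an
    episode is a maximal run of consecutive steps during which a given
    pair stays in contact, with lifetime = steps * dt.  Returns
    (episodes, summary) where summary holds mean/SD/min/max lifetimes.
    """
    open_at: dict = {}
    episodes: list[BondEpisode] = []
    n_steps = 0
    for step, contacts in enumerate(contacts_per_step):
        n_steps = step + 1
        current = set(tuple(c) for c in contacts)
        for pair in list(open_at):
            if pair not in current:
                start = open_at.pop(pair)
                episodes.append(BondEpisode(
                    spot=pair[0], motif=pair[1], start=start * dt,
                    end=step * dt, lifetime=(step - start) * dt))
        for pair in current:
            open_at.setdefault(pair, step)
    for pair, start in open_at.items():
        episodes.append(BondEpisode(
            spot=pair[0], motif=pair[1], start=start * dt,
            end=n_steps * dt, lifetime=(n_steps - start) * dt))
    lifetimes = np.array([e.lifetime for e in episodes])
    if len(lifetimes):
        summary = {"n": len(lifetimes), "mean": float(lifetimes.mean()),
                   "sd": float(lifetimes.std()), "min": float(lifetimes.min()),
                   "max": float(lifetimes.max())}
    else:
        summary = {"n": 0, "mean": float("nan"), "sd": float("nan"),
                   "min": float("nan"), "max": float("nan")}
    return episodes, summary


def occupancy(contacts_per_step, n_spots: int | None = None) -> float:
    """Mean number of simultaneously engaged binding spots, averaged
    over hydrophobically engaged steps only.

    A spot is engaged while it has >= 1 motif in contact.  Raises
    :class:`UndefinedObservableError` when no step is engaged (inert
    cargo or no contacts at all).
    """
    engaged_counts = []
    for contacts in contacts_per_step:
        spots = {c[0] for c in contacts}
        if n_spots is not None and len(spots) > n_spots:
            raise ValueError("more engaged spots than binding spots")
        if spots:
            engaged_counts.append(len(spots))
    if not engaged_counts:
        raise UndefinedObservableError(
            "occupancy undefined: no hydrophobically engaged steps")
    return float(np.mean(engaged_counts))


def shuttle_count(y_track: np.ndarray, entry_plane: float, mid_plane: float
                  ) -> int:
    """Completed entry -> mid-channel -> entry round trips.

    ``entry_plane`` is the cytoplasmic channel mouth and ``mid_plane``
    the axial channel midpoint (entry_plane > mid_plane along the
    import direction).  A round trip is counted each time the cargo,
    having reached the mid-channel plane, returns past the entry plane.
    """
    if entry_plane <= mid_plane:
        raise ValueError("entry plane must precede the mid-channel plane")
    count = 0
    reached_mid = False
    for y in np.asarray(y_track, float):
        if y <= mid_plane:
            reached_mid = True
        elif reached_mid and y >= entry_plane:
            count += 1
            reached_mid = False
    return count


def shuttle_fraction(records, frame) -> float:
    """Fraction of completed runs that shuttle at least once."""
    done = [r for r in records if r.completed]
    if not done:
        raise EmptyTrackError("no completed runs")
    n = sum(1 for r in done
            if shuttle_count(r.track[:, 1], frame.y_chan_top,
                             frame.y_chan_mid) >= 1)
    return n / len(done)


def channel_residence_fraction(record, frame=None) -> float:
    """Fraction of the first-passage time spent inside the central
    channel (cargo center between the channel entry and exit planes)."""
    if frame is None:
        frame = record.frame
    if not record.completed:
        raise UndefinedObservableError(
            "channel residence undefined for incomplete runs")
    t0 = record.t_start if record.t_start is not None else 0.0
    mask = (record.times >= t0) & (record.times <= record.t_end)
    if not mask.any():
        raise EmptyTrackError("no samples within the first-passage window")
    y = record.track[mask, 1]
    inside = (y <= frame.y_chan_top) & (y >= frame.y_chan_bot)
    return float(inside.mean())
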