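"""Synthetic data generators with known ground truth.

Four modalities are emulated, matching the inputs the analysis stages
consume:

* clustered + background single-molecule localization fields with
  consecutive-frame blinking and Gaussian localization error;
* single-particle trajectories switching among Brownian diffusive states
  under a Markov chain;
* dual-channel images of Gaussian puncta on Poisson background with a
  controlled fraction of cross-channel overlap;
* multichannel extracellular voltage traces with injected biphasic spike
  waveforms on Gaussian noise.

Every generator takes a ``seed`` and draws all randomness from one local
``numpy.random.Generator``; identical seeds and parameters give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import LocalizationTable, TrajectorySet

__all__ = [
    "SmlmGroundTruth",
    "SptGroundTruth",
    "SyntheticImagePair",
    "MEARecording",
    "simulate_smlm_field",
    "simulate_trajectories",
    "simulate_two_channel_image",
    "simulate_mea_recording",
    "default_spike_template",
    "stationary_distribution",
]


# ---------------------------------------------------------------------------
# SMLM localization fields
# ---------------------------------------------------------------------------

@dataclass
class SmlmGroundTruth:
    """Per-emitter and per-detection truth for a simulated SMLM field."""

    cluster_centers_nm: np.ndarray       # (n_clusters, 2)
    cluster_radius_nm: float
    localization_sigma_nm: float
    emitter_xy_nm: np.ndarray            # (n_emitters, 2)
    emitter_cluster_label: np.ndarray    # (n_emitters,), -1 = background
    detection_emitter_index: np.ndarray  # (n_detections,)
    detection_cluster_label: np.ndarray  # (n_detections,), -1 = background
    blink_repeat_mean: float = 2.0


def simulate_smlm_field(
    n_clusters: int,
    detections_per_cluster_mean: float = 60.0,
    cluster_radius_nm: float = 20.0,
    background_density_per_um2: float = 0.4,
    localization_sigma_nm: float = 10.0,
    n_frames: int = 20000,
    blink_repeat_mean: float = 2.0,
    field_width_nm: float = 10000.0,
    field_height_nm: float = 10000.0,
    seed: int | None = None,
) -> tuple[LocalizationTable, SmlmGroundTruth]:
    """Simulate a clustered + background localization field.

    Cluster centers are uniform in the field; emitters are uniform in discs
    of ``cluster_radius_nm`` around them.  Background emitters form a
    homogeneous Poisson field of ``background_density_per_um2`` (emitters
    per square micrometre).  Each emitter blinks for a geometric number of
    consecutive frames (mean ``blink_repeat_mean``), and every detection is
    jittered by isotropic Gaussian localization error of sd
    ``localization_sigma_nm``.  The expected number of detections per
    cluster is ``detections_per_cluster_mean`` (emitter count is Poisson
    with mean ``detections_per_cluster_mean / blink_repeat_mean``).
    """
    if field_width_nm <= 0 or field_height_nm <= 0:
        raise ValueError("field extent must be positive")
    if n_clusters < 0 or detections_per_cluster_mean < 0:
        raise ValueError("counts must be non-negative")
    if background_density_per_um2 < 0:
        raise ValueError("background density must be non-negative")
    if cluster_radius_nm <= 0:
        raise ValueError("cluster radius must be positive")
    if localization_sigma_nm < 0:
        raise ValueError("localization sigma must be non-negative")
    if blink_repeat_mean < 1:
        raise ValueError("blink_repeat_mean must be >= 1")

    rng = np.random.default_rng(seed)

    centers = rng.uniform(
        low=[0.0, 0.0], high=[field_width_nm, field_height_nm], size=(n_clusters, 2)
    )

    emitter_xy = []
    emitter_label = []
    mean_emitters = detections_per_cluster_mean / blink_repeat_mean
    for c in range(n_clusters):
        n_emit = rng.poisson(mean_emitters)
        # uniform in a disc
        r = cluster_radius_nm * np.sqrt(rng.uniform(size=n_emit))
        theta = rng.uniform(0, 2 * np.pi, size=n_emit)
        xy = centers[c] + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        emitter_xy.append(xy)
        emitter_label.append(np.full(n_emit, c, dtype=np.int64))

    area_um2 = field_width_nm * field_height_nm / 1e6
    n_bg = rng.poisson(background_density_per_um2 * area_um2)
    bg_xy = rng.uniform(
        low=[0.0, 0.0], high=[field_width_nm, field_height_nm], size=(n_bg, 2)
    )
    emitter_xy.append(bg_xy)
    emitter_label.append(np.full(n_bg, -1, dtype=np.int64))

    emitter_xy = (
        np.concatenate(emitter_xy) if emitter_xy else np.empty((0, 2))
    )
    emitter_label = (
        np.concatenate(emitter_label) if emitter_label else np.empty(0, dtype=np.int64)
    )
    n_emitters = len(emitter_xy)

    # blinking: geometric (support >= 1) number of consecutive frames
    if blink_repeat_mean == 1.0:
        n_det_per_emitter = np.ones(n_emitters, dtype=np.int64)
    else:
        n_det_per_emitter = rng.geometric(1.0 / blink_repeat_mean, size=n_emitters)
    start_frame = rng.integers(0, n_frames, size=n_emitters)
    # truncate chains at the end of the acquisition
    n_det_per_emitter = np.minimum(n_det_per_emitter, n_frames - start_frame)

    det_emitter = np.repeat(np.arange(n_emitters), n_det_per_emitter)
    offsets = np.concatenate(
        [np.arange(k) for k in n_det_per_emitter]
    ) if n_emitters else np.empty(0, dtype=np.int64)
    det_frame = start_frame[det_emitter] + offsets
    det_xy = emitter_xy[det_emitter] + rng.normal(
        scale=localization_sigma_nm, size=(len(det_emitter), 2)
    )
    # localization error never moves a detection outside the field of view
    det_xy[:, 0] = np.clip(det_xy[:, 0], 0.0, field_width_nm)
    det_xy[:, 1] = np.clip(det_xy[:, 1], 0.0, field_height_nm)

    order = np.lexsort((det_xy[:, 1], det_xy[:, 0], det_frame))
    locs = LocalizationTable(
        frame=det_frame[order],
        x_nm=det_xy[order, 0],
        y_nm=det_xy[order, 1],
        field_width_nm=field_width_nm,
        field_height_nm=field_height_nm,
    )
    truth = SmlmGroundTruth(
        cluster_centers_nm=centers,
        cluster_radius_nm=cluster_radius_nm,
        localization_sigma_nm=localization_sigma_nm,
        emitter_xy_nm=emitter_xy,
        emitter_cluster_label=emitter_label,
        detection_emitter_index=det_emitter[order],
        detection_cluster_label=emitter_label[det_emitter[order]]
        if len(det_emitter)
        else np.empty(0, dtype=np.int64),
        blink_repeat_mean=blink_repeat_mean,
    )
    return locs, truth


# ---------------------------------------------------------------------------
# Markov-switching Brownian trajectories
# ---------------------------------------------------------------------------

def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    A = np.asarray(A, dtype=np.float64)
    vals, vecs = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class SptGroundTruth:
    """True parameters and per-step hidden states of a trajectory simulation."""

    D_um2_s: np.ndarray
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    states: list = field(repr=False, default_factory=list)  # per-trajectory int arrays

    def state_fractions(self) -> np.ndarray:
        """Empirical fraction of displacement steps spent in each state."""
        all_states = np.concatenate(self.states)
        K = len(self.D_um2_s)
        return np.bincount(all_states, minlength=K) / len(all_states)


def simulate_trajectories(
    D_um2_s,
    transition_matrix,
    n_trajectories: int = 1000,
    lengths: int | np.ndarray = 10,
    dt_s: float = 0.020,
    localization_sigma_um: float = 0.0,
    seed: int | None = None,
) -> tuple[TrajectorySet, SptGroundTruth]:
    """Simulate trajectories switching among Brownian diffusive states.

    The hidden state chain is initialized from the stationary distribution
    of ``transition_matrix`` (steady-state assumption) and evolved per
    frame; each displacement component is Gaussian with variance
    ``2 * D[state] * dt_s``.  ``lengths`` is the number of positions per
    trajectory (scalar or per-trajectory array, all >= 2).  Optional
    Gaussian localization noise of sd ``localization_sigma_um`` is added to
    the reported positions.
    """
    D = np.atleast_1d(np.asarray(D_um2_s, dtype=np.float64))
    A = np.atleast_2d(np.asarray(transition_matrix, dtype=np.float64))
    K = len(D)
    if A.shape != (K, K):
        raise ValueError("transition matrix shape must match the number of states")
    if np.any(D < 0):
        raise ValueError("diffusion coefficients must be non-negative")
    if np.any(A < 0) or not np.allclose(A.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix must be row-stochastic")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")

    lengths = np.broadcast_to(
        np.asarray(lengths, dtype=np.int64), (n_trajectories,)
    ).copy()
    if np.any(lengths < 2):
        raise ValueError("every trajectory needs at least 2 positions")

    rng = np.random.default_rng(seed)
    pi = stationary_distribution(A)

    # simulate all chains padded to the maximum number of steps
    n_steps = lengths - 1
    T = int(n_steps.max()) if n_trajectories else 0
    states = np.zeros((n_trajectories, T), dtype=np.int64)
    if n_trajectories and T:
        u = rng.uniform(size=(n_trajectories, T))
        states[:, 0] = np.searchsorted(np.cumsum(pi), u[:, 0], side="right").clip(0, K - 1)
        cumA = np.cumsum(A, axis=1)
        for t in range(1, T):
            row = cumA[states[:, t - 1]]
            states[:, t] = (u[:, t, None] > row).sum(axis=1).clip(0, K - 1)

    sigma_step = np.sqrt(2.0 * D * dt_s)  # per-axis displacement sd by state
    disp = rng.normal(size=(n_trajectories, T, 2)) * sigma_step[states][..., None]

    tid, frames, xs, ys, true_states = [], [], [], [], []
    for i in range(n_trajectories):
        L = int(lengths[i])
        pos = np.zeros((L, 2))
        pos[1:] = np.cumsum(disp[i, : L - 1], axis=0)
        if localization_sigma_um > 0:
            pos = pos + rng.normal(scale=localization_sigma_um, size=pos.shape)
        tid.append(np.full(L, i, dtype=np.int64))
        frames.append(np.arange(L, dtype=np.int64))
        xs.append(pos[:, 0])
        ys.append(pos[:, 1])
        true_states.append(states[i, : L - 1].copy())

    traj = TrajectorySet(
        trajectory_id=np.concatenate(tid) if tid else np.empty(0, dtype=np.int64),
        frame=np.concatenate(frames) if frames else np.empty(0, dtype=np.int64),
        x_um=np.concatenate(xs) if xs else np.empty(0),
        y_um=np.concatenate(ys) if ys else np.empty(0),
        dt_s=dt_s,
    )
    truth = SptGroundTruth(
        D_um2_s=D, transition_matrix=A, initial_distribution=pi, states=true_states
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Dual-channel puncta images
# ---------------------------------------------------------------------------

@dataclass
class SyntheticImagePair:
    """Two-channel synthetic puncta image with ground-truth centers."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    pixel_size_nm: float
    centers_a: np.ndarray  # (n_a, 2) in (row, col) pixels
    centers_b: np.ndarray
    amplitude: float
    psf_sigma_px: float
    overlap_pairs: np.ndarray  # (n_overlap, 2) index pairs (a_idx, b_idx)


def _sample_separated(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    min_sep_px: float,
    margin_px: float,
    avoid: np.ndarray | None = None,
    avoid_sep_px: float = 0.0,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample n points with pairwise and cross-set separation."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place puncta with requested separation")
        p = rng.uniform(
            low=[margin_px, margin_px],
            high=[shape[0] - margin_px, shape[1] - margin_px],
        )
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < min_sep_px:
            continue
        if (
            avoid is not None
            and len(avoid)
            and np.min(np.linalg.norm(avoid - p, axis=1)) < avoid_sep_px
        ):
            continue
        pts.append(p)
    return np.array(pts) if pts else np.empty((0, 2))


def _render_spots(
    shape: tuple[int, int],
    centers: np.ndarray,
    amplitude: float,
    sigma: float,
) -> np.ndarray:
    img = np.zeros(shape, dtype=np.float64)
    half = int(np.ceil(4 * sigma))
    for r, c in centers:
        r0, c0 = int(round(r)), int(round(c))
        rr = np.arange(max(0, r0 - half), min(shape[0], r0 + half + 1))
        cc = np.arange(max(0, c0 - half), min(shape[1], c0 + half + 1))
        gr = np.exp(-((rr - r) ** 2) / (2 * sigma**2))
        gc = np.exp(-((cc - c) ** 2) / (2 * sigma**2))
        img[np.ix_(rr, cc)] += amplitude * gr[:, None] * gc[None, :]
    return img


def simulate_two_channel_image(
    shape: tuple[int, int] = (512, 512),
    pixel_size_nm: float = 100.0,
    n_puncta_a: int = 100,
    n_puncta_b: int = 100,
    overlap_fraction: float = 0.0,
    psf_sigma_px: float = 1.5,
    amplitude: float = 26.0,
    background_rate: float = 10.0,
    min_separation_px: float | None = None,
    seed: int | None = None,
) -> SyntheticImagePair:
    """Simulate a two-channel field of Gaussian puncta on Poisson background.

    ``round(overlap_fraction * n_puncta_a)`` channel-a puncta share centers
    (jittered by at most 1 px) with channel-b puncta.  Same-channel centers
    keep a minimum mutual distance (default ``8 * psf_sigma_px / 1.5``
    pixels) so that true puncta stay resolvable, and non-paired cross-channel
    centers stay at least ``5 * psf_sigma_px`` apart so that the generator's
    overlap fraction is the ground truth.  Pixel values are
    Poisson(background_rate + spot contribution).
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be positive")
    if background_rate < 0:
        raise ValueError("background_rate must be non-negative")

    rng = np.random.default_rng(seed)
    if min_separation_px is None:
        min_separation_px = 8.0 * psf_sigma_px / 1.5
    cross_sep = 5.0 * psf_sigma_px
    margin = 4.0 * psf_sigma_px

    centers_a = _sample_separated(rng, n_puncta_a, shape, min_separation_px, margin)
    n_overlap = int(round(overlap_fraction * n_puncta_a))
    n_overlap = min(n_overlap, n_puncta_b, n_puncta_a)

    paired_a = rng.choice(n_puncta_a, size=n_overlap, replace=False) if n_overlap else np.empty(0, dtype=np.int64)
    jitter = rng.uniform(-1.0, 1.0, size=(n_overlap, 2))
    jitter /= np.maximum(1.0, np.linalg.norm(jitter, axis=1, keepdims=True))  # |jitter| <= 1 px
    centers_b_paired = centers_a[paired_a] + jitter if n_overlap else np.empty((0, 2))

    n_free_b = n_puncta_b - n_overlap
    centers_b_free = _sample_separated(
        rng,
        n_free_b,
        shape,
        min_separation_px,
        margin,
        avoid=np.vstack([centers_a, centers_b_paired]) if (len(centers_a) or n_overlap) else None,
        avoid_sep_px=cross_sep,
    )
    centers_b = (
        np.vstack([centers_b_paired, centers_b_free])
        if (n_overlap or n_free_b)
        else np.empty((0, 2))
    )
    overlap_pairs = np.column_stack(
        [paired_a, np.arange(n_overlap)]
    ) if n_overlap else np.empty((0, 2), dtype=np.int64)

    lam_a = background_rate + _render_spots(shape, centers_a, amplitude, psf_sigma_px)
    lam_b = background_rate + _render_spots(shape, centers_b, amplitude, psf_sigma_px)
    img_a = rng.poisson(lam_a).astype(np.uint16)
    img_b = rng.poisson(lam_b).astype(np.uint16)

    return SyntheticImagePair(
        channel_a=img_a,
        channel_b=img_b,
        pixel_size_nm=pixel_size_nm,
        centers_a=centers_a,
        centers_b=centers_b,
        amplitude=amplitude,
        psf_sigma_px=psf_sigma_px,
        overlap_pairs=overlap_pairs,
    )


# ---------------------------------------------------------------------------
# MEA recordings
# ---------------------------------------------------------------------------

def default_spike_template(
    sampling_rate_hz: float = 10000.0, duration_ms: float = 1.6
) -> np.ndarray:
    """Biphasic extracellular spike waveform, peak absolute amplitude 1.

    A fast negative lobe followed by a slower positive rebound, the classic
    shape of an extracellular action potential near the soma.
    """
    n = max(4, int(round(duration_ms * 1e-3 * sampling_rate_hz)))
    t = np.arange(n) / sampling_rate_hz * 1e3  # ms
    w = -np.exp(-((t - 0.4) ** 2) / (2 * 0.1**2)) + 0.45 * np.exp(
        -((t - 0.8) ** 2) / (2 * 0.2**2)
    )
    return w / np.max(np.abs(w))


@dataclass
class MEARecording:
    """Multichannel extracellular traces with ground-truth spike times."""

    traces: np.ndarray  # (channels, samples) float32
    sampling_rate_hz: float
    duration_s: float
    true_spike_times_s: list = field(repr=False, default_factory=list)
    noise_sd: float = 1.0
    template: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]


def simulate_mea_recording(
    n_channels: int,
    rates_hz,
    duration_s: float = 600.0,
    sampling_rate_hz: float = 10000.0,
    spike_template: np.ndarray | None = None,
    spike_amplitude_sd_units: float = 12.0,
    noise_sd: float = 1.0,
    spike_times_s: list | None = None,
    seed: int | None = None,
) -> MEARecording:
    """Simulate extracellular traces with Poisson spiking on Gaussian noise.

    Each channel fires as a homogeneous Poisson process at its rate; every
    spike adds the biphasic ``spike_template`` scaled to a peak amplitude of
    ``spike_amplitude_sd_units * noise_sd`` onto white Gaussian noise of sd
    ``noise_sd``.  Overlapping templates sum linearly (no refractory
    enforcement in the generator), so spikes closer than the template
    duration collide but both remain in the ground truth.  Ground-truth
    spike times (the sample of the template's absolute peak) are returned
    per channel.  ``spike_times_s`` (per-channel arrays of template peak
    times) overrides the Poisson draw for constructed inputs.
    """
    if duration_s <= 0 or sampling_rate_hz <= 0:
        raise ValueError("duration and sampling rate must be positive")
    rates = np.broadcast_to(np.asarray(rates_hz, dtype=np.float64), (n_channels,))
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    if spike_template is None:
        spike_template = default_spike_template(sampling_rate_hz)
    template = np.asarray(spike_template, dtype=np.float64)
    n_samples = int(round(duration_s * sampling_rate_hz))
    if len(template) >= n_samples:
        raise ValueError("spike template longer than the trace")
    peak_offset = int(np.argmax(np.abs(template)))

    rng = np.random.default_rng(seed)
    traces = np.empty((n_channels, n_samples), dtype=np.float32)
    true_times: list[np.ndarray] = []
    amp = spike_amplitude_sd_units * noise_sd
    for ch in range(n_channels):
        x = rng.normal(scale=noise_sd, size=n_samples)
        if spike_times_s is not None:
            peaks = np.round(np.asarray(spike_times_s[ch]) * sampling_rate_hz).astype(np.int64)
            starts = np.sort(peaks - peak_offset)
            if len(starts) and (starts.min() < 0 or starts.max() > n_samples - len(template)):
                raise ValueError("forced spike does not fit inside the trace")
        else:
            n_spikes = rng.poisson(rates[ch] * duration_s)
            # spike insertion start sample; whole template must fit in the trace
            starts = np.sort(
                rng.integers(0, n_samples - len(template), size=n_spikes)
            )
        for s in starts:
            x[s : s + len(template)] += amp * template
        traces[ch] = x.astype(np.float32)
        true_times.append((starts + peak_offset) / sampling_rate_hz)

    return MEARecording(
        traces=traces,
        sampling_rate_hz=sampling_rate_hz,
        duration_s=duration_s,
        true_spike_times_s=true_times,
        noise_sd=noise_sd,
        template=template,
    )
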