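"""Synthetic two-condition, two-ROI epoched data for connectivity testing.

The generator emulates a paired MEG/EEG connectivity experiment at the
sub-ROI level.  Each of two regions of interest (ROI1, ROI2) is divided
into ``n_subrois_per_roi`` sub-ROIs, each represented by one time series
per epoch.  In condition 1 a Hann-windowed multi-frequency sinusoidal
burst (15-20 Hz, 200-400 ms by default) is injected into a subset of
"active" sub-ROIs of *both* ROIs, so the two regions carry genuine
inter-regional coherence; the burst rides on broadband 1/f background
noise.  Condition 2 is background noise only.  The broadband noise mixes
an idiosyncratic 1/f process per sub-ROI with a low-amplitude component
shared across all sub-ROIs, inducing the weak baseline coherence seen
between real brain regions at rest.

Three spatial layouts of the active sub-ROIs are supported:

``continuous``
    the first ``n_active_subrois`` sub-ROIs of each ROI (default {0,1,2});
``scattered``
    spatially discontinuous sub-ROIs, pairwise non-adjacent
    (default {0,3,6});
``variable``
    per-subject random active sets, constrained to be non-adjacent in
    ROI2 and to differ across subjects.

SNR is reported in dB as ``20*log10(S/N)`` where S is the mean absolute
signal amplitude over all channels inside the signal window and N is the
mean absolute background-noise amplitude over all channels and times.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimulationScenario",
    "EpochSet",
    "SyntheticDataset",
    "hann_burst",
    "pink_noise",
    "noise_segments",
    "compute_snr",
    "build_dataset",
]

#: default burst frequency set Omega (Hz)
DEFAULT_FREQ_SET = tuple(range(15, 21))

#: role -> RNG stream key for the per-subject noise draws; the two draws
#: per condition play the roles of the independent resting segments R1, R2
_NOISE_STREAMS = {"c1_r1": 0, "c1_r2": 1, "c2_r1": 2, "c2_r2": 3}

_SCENARIO_TYPES = ("continuous", "scattered", "variable")


@dataclass
class SimulationScenario:
    """Full generative configuration for one synthetic dataset.

    Defaults are the package's canonical study conditions: 8 subjects, 9
    sub-ROIs per ROI, 50 epochs per condition on a -250..750 ms window
    sampled at 600 Hz, a 15-20 Hz burst confined to 200-400 ms, and a
    signal scale drawn uniformly from [0.04, 0.1] (``signal_scale=None``)
    with noise fraction beta ~ U(0, 1) (``noise_fraction=None``).
    """

    n_subjects: int = 8
    n_subrois_per_roi: int = 9
    n_epochs: int = 50
    epoch_window: tuple[float, float] = (-0.250, 0.750)
    signal_window: tuple[float, float] = (0.200, 0.400)
    freq_set: tuple[float, ...] = DEFAULT_FREQ_SET
    q0: float = 10.0  # source strength, abstract amplitude units
    signal_scale: float | None = None  # alpha_sig; None -> U(0.04, 0.1)
    noise_fraction: float | None = None  # beta; None -> U(0, 1)
    scenario_type: str = "continuous"
    n_active_subrois: int = 3
    active_subrois: dict | None = None  # explicit per-subject override
    sampling_rate: float = 600.0
    noise_scale: float = 0.03  # background-noise std, same units as q0*signal_scale
    shared_noise_weight: float = 0.2
    noise_slope: float = 1.0  # power-law exponent of the noise spectrum
    rng_seed: int = 0

    # -- derived -----------------------------------------------------
    @property
    def times(self) -> np.ndarray:
        """Sample times (s), half-open interval [t_start, t_end)."""
        t0, t1 = self.epoch_window
        n = int(round((t1 - t0) * self.sampling_rate))
        return t0 + np.arange(n) / self.sampling_rate

    @property
    def n_channels(self) -> int:
        return 2 * self.n_subrois_per_roi

    @property
    def roi_membership(self) -> np.ndarray:
        """0 for ROI1 sub-ROIs, 1 for ROI2; ROI1 channels come first."""
        return np.repeat([0, 1], self.n_subrois_per_roi)

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_epochs < 1:
            raise ValueError("need at least one subject and one epoch")
        if self.n_subrois_per_roi < 1:
            raise ValueError("need at least one sub-ROI per ROI")
        if self.scenario_type not in _SCENARIO_TYPES:
            raise ValueError(
                f"scenario_type must be one of {_SCENARIO_TYPES}, "
                f"got {self.scenario_type!r}"
            )
        t0, t1 = self.epoch_window
        s0, s1 = self.signal_window
        if not (t0 <= s0 < s1 <= t1):
            raise ValueError("signal_window must lie inside epoch_window")
        if len(self.freq_set) == 0:
            raise ValueError("freq_set must be non-empty")
        if self.signal_scale is not None and self.signal_scale < 0:
            raise ValueError("signal_scale must be >= 0")
        if self.noise_fraction is not None and not 0 <= self.noise_fraction <= 1:
            raise ValueError("noise_fraction must be in [0, 1]")
        if not 0 < self.n_active_subrois <= self.n_subrois_per_roi:
            raise ValueError("n_active_subrois out of range")
        if self.active_subrois is not None:
            for sets in self.active_subrois.values():
                for idx_set in sets:
                    if any(i >= self.n_subrois_per_roi for i in idx_set):
                        raise ValueError("active sub-ROI index out of range")


@dataclass
class EpochSet:
    """Epoched sub-ROI time series for one subject and condition.

    ``data`` has shape (n_subrois, n_epochs, n_times); ``roi_membership``
    maps sub-ROI index to ROI label (0 = ROI1, 1 = ROI2).
    """

    subject_id: int
    condition_id: str
    data: np.ndarray
    times: np.ndarray
    roi_membership: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.roi_membership = np.asarray(self.roi_membership, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_subrois, n_epochs, n_times)")
        if self.data.shape[0] != self.roi_membership.size:
            raise ValueError("roi_membership length != number of sub-ROIs")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length != data time axis")
        dt = np.diff(self.times)
        if self.times.size > 1 and not (
            np.all(dt > 0) and np.allclose(dt, dt[0], rtol=1e-6)
        ):
            raise ValueError("time axis must be strictly increasing and uniform")

    @property
    def roi_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.flatnonzero(self.roi_membership == 0),
            np.flatnonzero(self.roi_membership == 1),
        )


@dataclass
class SyntheticDataset:
    """A full simulated study: all subjects, both conditions.

    Carries the realized SNR and the drawn nuisance parameters so power
    curves can be plotted against the actual, not nominal, SNR.
    """

    epoch_sets: list[EpochSet]
    scenario: SimulationScenario
    snr_db: float
    signal_scale: float
    noise_fraction: float
    active_subrois: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.epoch_sets)

    def __len__(self):
        return len(self.epoch_sets)


def hann_burst(times, signal_window, freq_set, q0=1.0) -> np.ndarray:
    """Hann-windowed equal-weight sum of sinusoids, zero outside the window.

    Returns ``q0/F * sum_f w(t - t_on) * sin(2*pi*f*(t - t_on))`` inside
    ``signal_window`` and exactly zero elsewhere, with ``w`` the Hann
    window ``0.5*(1 - cos(2*pi*tau/T))`` over the window duration T.
    """
    times = np.asarray(times, dtype=float)
    freq_set = tuple(freq_set)
    if len(freq_set) == 0:
        raise ValueError("freq_set must be non-empty")
    t_on, t_off = signal_window
    # allow t_off one sample past the last time of a half-open epoch window
    dt = float(np.median(np.diff(times))) if times.size > 1 else 0.0
    if t_on < times[0] - 1e-12 or t_off > times[-1] + dt + 1e-12:
        raise ValueError("signal_window outside the epoch time range")
    if not t_off > t_on:
        raise ValueError("signal_window must have positive duration")
    T = t_off - t_on
    tau = times - t_on
    inside = (times >= t_on - 1e-12) & (times <= t_off + 1e-12)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / T))
    carriers = np.zeros_like(times)
    for f in freq_set:
        carriers = carriers + np.sin(2.0 * np.pi * f * tau)
    out = np.where(inside, q0 / len(freq_set) * w * carriers, 0.0)
    return out


def pink_noise(rng, shape, n_times, sampling_rate, slope=1.0) -> np.ndarray:
    """Unit-variance power-law noise, power spectrum ~ 1/f**slope.

    Synthesized in the Fourier domain with independent complex-Gaussian
    bins; the normalization to unit variance is analytic (deterministic),
    not empirical, so the spectral statistics are unbiased.
    """
    shape = tuple(shape)
    n_f = n_times // 2 + 1
    f = np.fft.rfftfreq(n_times, 1.0 / sampling_rate)
    amp = np.zeros(n_f)
    amp[1:] = f[1:] ** (-slope / 2.0)
    z = amp * (
        rng.standard_normal(shape + (n_f,)) + 1j * rng.standard_normal(shape + (n_f,))
    )
    z[..., 0] = 0.0
    if n_times % 2 == 0:
        z[..., -1] = z[..., -1].real  # Nyquist bin must be real
        expected_var = (4.0 * np.sum(amp[1:-1] ** 2) + amp[-1] ** 2) / n_times**2
    else:
        expected_var = 4.0 * np.sum(amp[1:] ** 2) / n_times**2
    x = np.fft.irfft(z, n=n_times)
    return x / np.sqrt(expected_var)


def noise_segments(scenario, subject, n_epochs=None, stream="c1_r2") -> np.ndarray:
    """One background-noise draw for a subject: (n_channels, n_epochs, n_times).

    ``stream`` selects one of four disjoint deterministic RNG streams per
    subject ("c1_r1", "c1_r2", "c2_r1", "c2_r2"); the two draws per
    condition play the roles of the independent resting segments R1 and
    R2.  Output is bit-identical for identical (seed, subject, stream).
    """
    if stream not in _NOISE_STREAMS:
        raise ValueError(f"unknown noise stream {stream!r}")
    sc = scenario
    n_epochs = sc.n_epochs if n_epochs is None else int(n_epochs)
    n_times = sc.times.size
    ss = np.random.SeedSequence(
        sc.rng_seed, spawn_key=(int(subject), _NOISE_STREAMS[stream])
    )
    rng = np.random.default_rng(ss)
    idio = pink_noise(
        rng, (sc.n_channels, n_epochs), n_times, sc.sampling_rate, sc.noise_slope
    )
    w = sc.shared_noise_weight
    if w != 0.0:
        shared = pink_noise(rng, (n_epochs,), n_times, sc.sampling_rate, sc.noise_slope)
        mixed = (idio + w * shared[np.newaxis]) / np.sqrt(1.0 + w**2)
    else:
        mixed = idio
    return sc.noise_scale * mixed


def compute_snr(signal, noise, signal_window, times) -> float:
    """SNR in dB: 20*log10(S/N).

    S = mean absolute signal value over all channels within
    ``signal_window``; N = mean absolute noise value over all channels
    and all time points.  The time axis is the trailing axis of both
    arrays.
    """
    signal = np.asarray(signal, dtype=float)
    noise = np.asarray(noise, dtype=float)
    times = np.asarray(times, dtype=float)
    t_on, t_off = signal_window
    win = (times >= t_on - 1e-12) & (times <= t_off + 1e-12)
    if not np.any(win):
        raise ValueError("signal_window contains no samples")
    s = float(np.mean(np.abs(signal[..., win])))
    n = float(np.mean(np.abs(noise)))
    if n == 0.0:
        raise ValueError("noise is identically zero; SNR undefined")
    if s == 0.0:
        return -np.inf
    return 20.0 * np.log10(s / n)


# ---------------------------------------------------------------------
# active sub-ROI layouts


def _nonadjacent_triples(n, k):
    """All sorted k-subsets of range(n) with pairwise index gaps >= 2."""
    return [
        c
        for c in itertools.combinations(range(n), k)
        if all(b - a >= 2 for a, b in zip(c, c[1:]))
    ]


def _resolve_active(scenario, rng):
    """Per-subject active sub-ROI sets: {subject: (roi1_set, roi2_set)}."""
    sc = scenario
    if sc.active_subrois is not None:
        return {int(s): (tuple(v[0]), tuple(v[1])) for s, v in sc.active_subrois.items()}
    k, n = sc.n_active_subrois, sc.n_subrois_per_roi
    if sc.scenario_type == "continuous":
        sets = tuple(range(k))
        return {s: (sets, sets) for s in range(sc.n_subjects)}
    if sc.scenario_type == "scattered":
        spaced = tuple(range(0, 3 * k, 3))
        if spaced[-1] >= n:
            spaced = tuple(_nonadjacent_triples(n, k)[0])
        return {s: (spaced, spaced) for s in range(sc.n_subjects)}
    # variable: ROI1's active set is drawn once at random and shared by all
    # subjects; ROI2's sets are per-subject, non-adjacent, and pairwise
    # distinct across subjects, so the active pair layout varies by subject
    candidates2 = _nonadjacent_triples(n, k)
    if len(candidates2) < sc.n_subjects:
        raise ValueError(
            "not enough distinct non-adjacent active sets for this many subjects"
        )
    roi1 = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
    chosen = rng.choice(len(candidates2), size=sc.n_subjects, replace=False)
    return {s: (roi1, tuple(candidates2[c])) for s, c in enumerate(chosen)}


def build_dataset(scenario, target_snr_db=None) -> SyntheticDataset:
    """Generate the full study: all subjects x both conditions.

    Condition 1 is ``alpha_sig * burst + beta * R1 + R2`` in the active
    sub-ROIs and ``beta * R1 + R2`` elsewhere; condition 2 is an
    independent draw ``beta * R1' + R2'`` from the same noise law, so
    with ``alpha_sig = 0`` the two conditions are exchangeable by
    construction.  If ``target_snr_db`` is given, the signal scale is
    solved (exactly, by linearity) so the realized SNR equals the target,
    overriding ``scenario.signal_scale``.
    """
    sc = scenario
    sc.validate()
    par_rng = np.random.default_rng(np.random.SeedSequence(sc.rng_seed, spawn_key=(1000,)))
    alpha_sig = (
        float(par_rng.uniform(0.04, 0.1))
        if sc.signal_scale is None
        else float(sc.signal_scale)
    )
    beta = (
        float(par_rng.uniform(0.0, 1.0))
        if sc.noise_fraction is None
        else float(sc.noise_fraction)
    )
    active = _resolve_active(sc, par_rng)

    times = sc.times
    burst = hann_burst(times, sc.signal_window, sc.freq_set, sc.q0)
    n1 = sc.n_subrois_per_roi

    fields, c1_noises, c2_all = [], [], []
    for s in range(sc.n_subjects):
        r1a = noise_segments(sc, s, stream="c1_r1")
        r2a = noise_segments(sc, s, stream="c1_r2")
        r1b = noise_segments(sc, s, stream="c2_r1")
        r2b = noise_segments(sc, s, stream="c2_r2")
        field_s = np.zeros((sc.n_channels, times.size))
        roi1_set, roi2_set = active[s]
        ch = list(roi1_set) + [n1 + j for j in roi2_set]
        field_s[ch] = burst  # identical waveform in every active sub-ROI
        fields.append(field_s)
        c1_noises.append(beta * r1a + r2a)
        c2_all.append(beta * r1b + r2b)

    fields = np.stack(fields)
    c2_stack = np.stack(c2_all)
    if target_snr_db is not None:
        # realized SNR is 20*log10(alpha*S1/N) with S1, N fixed by the draws
        t_on, t_off = sc.signal_window
        win = (times >= t_on - 1e-12) & (times <= t_off + 1e-12)
        s1 = float(np.mean(np.abs(fields[..., win])))
        n_lvl = float(np.mean(np.abs(c2_stack)))
        if s1 == 0.0:
            raise ValueError("cannot calibrate SNR: signal field is zero")
        alpha_sig = n_lvl / s1 * 10.0 ** (target_snr_db / 20.0)

    epoch_sets = []
    for s in range(sc.n_subjects):
        c1 = alpha_sig * fields[s][:, np.newaxis, :] + c1_noises[s]
        for cond, data in (("C1", c1), ("C2", c2_all[s])):
            epoch_sets.append(
                EpochSet(
                    subject_id=s,
                    condition_id=cond,
                    data=data,
                    times=times,
                    roi_membership=sc.roi_membership,
                    sampling_rate=sc.sampling_rate,
                )
            )
    snr_db = compute_snr(alpha_sig * fields, c2_stack, sc.signal_window, times)
    return SyntheticDataset(
        epoch_sets=epoch_sets,
        scenario=replace(sc),
        snr_db=snr_db,
        signal_scale=alpha_sig,
        noise_fraction=beta,
        active_subrois=active,
    )
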