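"""Frequency-domain characterisation and comparison of stochastic ensembles.

The pipeline is: resample each irregular event trajectory onto a regular grid
by last-value (LOCF) sampling, take the discrete Fourier transform of the N
samples, keep the per-bin amplitudes (moduli), and average the amplitude
spectra term-wise over an ensemble of K runs.  Averaging *amplitudes* rather
than the complex spectra is essential: the DFT is linear, so averaging complex
spectra is the same as transforming the time-domain ensemble mean, in which
oscillations of randomly drifting phase cancel and behavioural structure is
lost.  The amplitude average discards phase and preserves it.

Two ensembles are compared per species by a discrete Kolmogorov-Smirnov
distance: each average amplitude spectrum is normalised to unit mass, the
cumulative distributions over ascending frequency are formed, and

    D = max |F_1 - F_2|,    D in [0, 1],  D = 0 for identical spectra.

With N samples a time step ``dt`` apart, the observation window is ``N*dt``,
the frequency resolution ``1/(N*dt)`` and the maximum observable frequency
``1/(2*dt)``.  The defaults N=4000, dt=1 min, K=100 resolve differences in D
of about 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import ReactionNetwork
from .ssa import SimConfig, Trajectory, derive_seed, iter_ensemble

__all__ = [
    "SamplingConfig",
    "SampledSeries",
    "AmplitudeSpectrum",
    "AverageSpectrum",
    "KSResult",
    "resample",
    "amplitude_spectrum",
    "phase_spectrum",
    "average_spectrum",
    "ks_distance",
    "procedure_A",
    "procedure_B",
    "procedure_B_full",
    "convergence_cov",
    "DEFAULT_N",
    "DEFAULT_DT",
    "DEFAULT_K",
]

DEFAULT_N = 4000
DEFAULT_DT = 1.0
DEFAULT_K = 100


@dataclass(frozen=True)
class SamplingConfig:
    """Regular sampling grid: N samples, dt minutes apart."""

    N: int = DEFAULT_N
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def window(self) -> float:
        """Total observed time N*dt (minutes)."""
        return self.N * self.dt

    @property
    def resolution(self) -> float:
        """Frequency resolution 1/(N*dt) (cycles/min)."""
        return 1.0 / (self.N * self.dt)

    @property
    def max_frequency(self) -> float:
        """Maximum observable frequency 1/(2*dt) (cycles/min)."""
        return 1.0 / (2.0 * self.dt)

    def frequencies(self) -> np.ndarray:
        """One-sided frequency grid, bins 0..floor(N/2), cycles/min."""
        return np.fft.rfftfreq(self.N, d=self.dt)


@dataclass
class SampledSeries:
    """N regular samples of one species from one trajectory."""

    values: np.ndarray
    config: SamplingConfig
    species: str = ""


@dataclass
class AmplitudeSpectrum:
    """One-sided amplitude spectrum |f_w| with its frequency grid."""

    amplitudes: np.ndarray
    config: SamplingConfig
    species: str = ""

    @property
    def frequencies(self) -> np.ndarray:
        return self.config.frequencies()

    def dominant_frequency(self, exclude_dc: bool = True) -> float:
        """Frequency of the largest bin (optionally skipping the DC bin)."""
        amps = self.amplitudes
        start = 1 if exclude_dc else 0
        return float(self.frequencies[start + int(np.argmax(amps[start:]))])


class AverageSpectrum:
    """Running term-wise mean of amplitude spectra over an ensemble.

    Uses Welford accumulation so runs can be added incrementally (Procedure A
    step 3, "adding new simulations to the average as necessary") while
    agreeing with the batch mean to floating-point accuracy.  Per-bin second
    moments are kept for the coefficient-of-variation stopping criterion.
    """

    def __init__(self, config: SamplingConfig, species: str = ""):
        self.config = config
        self.species = species
        self.K = 0
        n_bins = config.N // 2 + 1
        self._mean = np.zeros(n_bins)
        self._m2 = np.zeros(n_bins)

    def add(self, spectrum: AmplitudeSpectrum) -> "AverageSpectrum":
        if spectrum.config != self.config:
            raise ValueError("spectrum grid does not match (N, dt)")
        self.K += 1
        delta = spectrum.amplitudes - self._mean
        self._mean += delta / self.K
        self._m2 += delta * (spectrum.amplitudes - self._mean)
        return self

    @property
    def means(self) -> np.ndarray:
        if self.K == 0:
            raise ValueError("no spectra averaged yet")
        return self._mean

    @property
    def frequencies(self) -> np.ndarray:
        return self.config.frequencies()

    def bin_std(self) -> np.ndarray:
        """Per-bin sample standard deviation (ddof=1) across runs."""
        if self.K < 2:
            raise ValueError("need K >= 2 for a standard deviation")
        return np.sqrt(self._m2 / (self.K - 1))

    def dominant_frequency(self, exclude_dc: bool = True) -> float:
        start = 1 if exclude_dc else 0
        return float(self.frequencies[start + int(np.argmax(self.means[start:]))])


@dataclass
class KSResult:
    """Kolmogorov-Smirnov behavioural distance between two average spectra."""

    D: float
    cdf_a: np.ndarray
    cdf_b: np.ndarray


def resample(
    traj: Trajectory, cfg: SamplingConfig, species: str | Sequence[str]
) -> SampledSeries | dict[str, SampledSeries]:
    """Last-value sampling: x_n is the state at the latest event time <= n*dt.

    If the trajectory terminated before the end of the grid (absorbing state),
    the final value is carried forward.  Pass one species name for a single
    series or a sequence for a dict of series.
    """
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    grid = np.arange(cfg.N) * cfg.dt
    # index of last event time <= grid point; times[0]=0 so index >= 0
    pos = np.searchsorted(traj.times, grid, side="right") - 1
    single = isinstance(species, str)
    names = [species] if single else list(species)
    out = {}
    for name in names:
        col = traj.species_order.index(name)
        out[name] = SampledSeries(traj.states[pos, col].astype(float), cfg, name)
    return out[species] if single else out


def _dft(series: SampledSeries) -> np.ndarray:
    x = np.asarray(series.values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite sample values")
    return np.fft.rfft(x)


def amplitude_spectrum(series: SampledSeries) -> AmplitudeSpectrum:
    """One-sided DFT amplitude spectrum of the raw samples.

    No windowing, detrending or normalisation is applied: the DC bin and the
    low-frequency transient are part of the behavioural signature.  Bins
    0..floor(N/2) are retained; for real input the remaining bins are the
    complex conjugates and carry no extra information.
    """
    return AmplitudeSpectrum(np.abs(_dft(series)), series.config, series.species)


def phase_spectrum(series: SampledSeries, tol: float | None = None):
    """Per-bin four-quadrant phase in (-pi, pi].

    Returns ``(phases, defined)`` where ``defined`` is False for bins whose
    amplitude is below ``tol`` (default ``1e-9 * N * max|x|``), at which the
    phase is numerically meaningless.
    """
    f = _dft(series)
    if tol is None:
        tol = 1e-9 * series.config.N * max(float(np.max(np.abs(series.values))), 1.0)
    return np.angle(f), np.abs(f) >= tol


def average_spectrum(
    spectra: Iterable[AmplitudeSpectrum], species: str = ""
) -> AverageSpectrum:
    """Term-wise arithmetic mean of amplitude spectra sharing one grid."""
    avg: AverageSpectrum | None = None
    for sp in spectra:
        if avg is None:
            avg = AverageSpectrum(sp.config, species or sp.species)
        avg.add(sp)
    if avg is None:
        raise ValueError("no spectra given")
    return avg


def _unit_mass(amps: np.ndarray) -> np.ndarray:
    total = float(amps.sum())
    if total <= 0:
        raise ValueError("all-zero spectrum has no distribution")
    return amps / total


def ks_distance(
    a: AverageSpectrum | AmplitudeSpectrum | np.ndarray,
    b: AverageSpectrum | AmplitudeSpectrum | np.ndarray,
) -> KSResult:
    """Discrete K-S distance between two spectra on the same frequency grid.

    Each spectrum is normalised to unit sum, cumulative sums are formed over
    ascending frequency, and D is the maximum absolute difference.
    """
    amps_a = _spectrum_values(a)
    amps_b = _spectrum_values(b)
    if amps_a.shape != amps_b.shape:
        raise ValueError("spectra are on different frequency grids")
    cfg_a, cfg_b = _spectrum_config(a), _spectrum_config(b)
    if cfg_a is not None and cfg_b is not None and cfg_a != cfg_b:
        raise ValueError("spectra are on different frequency grids")
    F_a = np.cumsum(_unit_mass(amps_a))
    F_b = np.cumsum(_unit_mass(amps_b))
    return KSResult(float(np.max(np.abs(F_a - F_b))), F_a, F_b)


def _spectrum_values(s) -> np.ndarray:
    if isinstance(s, AverageSpectrum):
        return s.means
    if isinstance(s, AmplitudeSpectrum):
        return s.amplitudes
    return np.asarray(s, dtype=float)


def _spectrum_config(s):
    return getattr(s, "config", None)


def convergence_cov(
    avg: AverageSpectrum, threshold: float = 0.05, mean_floor: float | None = None
) -> tuple[np.ndarray, bool]:
    """Coefficient of variation of each spectral-bin mean, and pass/fail.

    CoV of the mean = (sample std / sqrt(K)) / mean per bin.  The ensemble is
    judged converged when every bin whose mean exceeds ``mean_floor`` (default
    1% of the largest bin mean) satisfies CoV <= threshold; near-empty bins
    are excluded because their relative error is irrelevant to D.
    """
    if avg.K < 2:
        raise ValueError("need K >= 2 runs to assess convergence")
    mean = avg.means
    sem = avg.bin_std() / np.sqrt(avg.K)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(mean > 0, sem / mean, np.inf)
    if mean_floor is None:
        mean_floor = 0.01 * float(mean.max())
    relevant = mean > mean_floor
    passed = bool(np.all(cov[relevant] <= threshold))
    return cov, passed


# ---------------------------------------------------------------------------
# Procedures A and B


def _spectra_for_run(traj, sampling, species_list):
    series = resample(traj, sampling, species_list)
    return {name: amplitude_spectrum(series[name]) for name in species_list}


def procedure_A(
    net: ReactionNetwork,
    sim_cfg: SimConfig,
    sampling: SamplingConfig,
    K: int = DEFAULT_K,
    base_seed: int = 0,
    species_list: Sequence[str] | None = None,
    averages: Mapping[str, AverageSpectrum] | None = None,
    start_run: int = 0,
) -> dict[str, AverageSpectrum]:
    """Average amplitude spectrum per species over a K-run ensemble.

    Runs K simulations seeded from ``(base_seed, start_run + i)``, resamples
    each trajectory, transforms it and accumulates the per-species average.
    Pass previous ``averages`` together with ``start_run`` to extend an
    existing ensemble with further runs.
    """
    if species_list is None:
        species_list = net.species_names
    missing = [s for s in species_list if s not in net.species_names]
    if missing:
        raise KeyError(f"species not in network: {missing}")
    avgs = dict(averages) if averages else {
        name: AverageSpectrum(sampling, name) for name in species_list
    }
    for i in range(K):
        run_cfg = SimConfig(
            sim_cfg.t_max, derive_seed(base_seed, start_run + i),
            sim_cfg.record, sim_cfg.max_events,
        )
        from .ssa import simulate

        traj = simulate(net, run_cfg)
        for name, spec in _spectra_for_run(traj, sampling, species_list).items():
            avgs[name].add(spec)
    return avgs


def procedure_B(
    net_a: ReactionNetwork,
    net_b: ReactionNetwork,
    sim_cfg: SimConfig,
    sampling: SamplingConfig,
    K: int = DEFAULT_K,
    base_seed: int = 0,
    species_list: Sequence[str] | None = None,
    shared_seeds: bool = False,
) -> dict[str, float]:
    """Per-species behavioural distance D between two simulated conditions.

    Runs paired ensembles of K runs each (pair i of side a and side b share
    the pairing index but use independent derived seeds unless
    ``shared_seeds``), averages amplitude spectra per side and returns
    ``{species: D}``.  The full result, including both averages, is available
    via :func:`procedure_B_full`.
    """
    return procedure_B_full(
        net_a, net_b, sim_cfg, sampling, K, base_seed, species_list, shared_seeds
    )[0]


def procedure_B_full(
    net_a, net_b, sim_cfg, sampling, K=DEFAULT_K, base_seed=0,
    species_list=None, shared_seeds=False,
):
    if species_list is None:
        species_list = [s for s in net_a.species_names if s in net_b.species_names]
    for side, net in (("a", net_a), ("b", net_b)):
        missing = [s for s in species_list if s not in net.species_names]
        if missing:
            raise KeyError(f"species missing from network {side}: {missing}")
    # independent per-side seed streams derived from one base seed
    seed_a = derive_seed(base_seed, 0xA)
    seed_b = seed_a if shared_seeds else derive_seed(base_seed, 0xB)
    avgs_a = procedure_A(net_a, sim_cfg, sampling, K, seed_a, species_list)
    avgs_b = procedure_A(net_b, sim_cfg, sampling, K, seed_b, species_list)
    D = {
        name: ks_distance(avgs_a[name], avgs_b[name]).D for name in species_list
    }
    return D, avgs_a, avgs_b
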