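"""Synthetic multi-wavelength ΔA(λ, t) trace generation.

Emulates the three instrument regimes of a flash-photolysis laboratory:

* ``ps_ns`` — sub-ns excitation, ~200 ps Gaussian response, log grid to 20 ns;
* ``ns_us`` — 5 ns excitation pulses, log grid to ~80 μs;
* ``ms_s``  — lamp/filter detection, ~30 μs response, grid sized to the
  slowest time constant of the scheme.

A trace set is composed by Beer–Lambert superposition of the kinetic
states' difference spectra versus the ground state,

    ΔA(λ, t) = c_pair · d · Σ_s p_s(t) · Δε_s(λ),

with the exact multi-exponential solution of the kinetic network convolved
analytically (exponential ⊗ Gaussian) with the instrument response, plus
optional additive white Gaussian noise and an optional hydrated-electron
artifact (a UV-excitation by-product absorbing near 720 nm).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import scipy.special

from . import photocycle as pc
from . import spectra as sp

__all__ = [
    "InstrumentSetup",
    "TraceSet",
    "REGIME_IRF_FWHM",
    "PROBE_WAVELENGTHS",
    "default_time_grid",
    "gaussian_convolved_decay",
    "convolve_irf",
    "trace_from_trajectory",
    "state_difference_matrix",
    "add_electron_artifact",
    "generate_dataset",
    "noise_sigma_for_fraction",
]

REGIMES = ("ps_ns", "ns_us", "ms_s")

#: Default instrument-response FWHM per regime (s).
REGIME_IRF_FWHM = {"ps_ns": 200e-12, "ns_us": 5e-9, "ms_s": 30e-6}

#: Representative probe wavelength sets (nm).  The published experiments
#: name 380, 408, 450, 457, 540, 562, 594, 610 and 630 nm as diagnostic
#: wavelengths; these sets group them per experiment type.
PROBE_WAVELENGTHS: dict[str, tuple[int, ...]] = {
    "wt_ns_us": (375, 408, 450, 457, 510, 562, 594),
    "wt_ps_ns": (408, 457, 510, 562, 594),
    "wt_ms": (408, 450, 510, 540),
    "w388f_ns_us": (375, 408, 450, 457, 510, 562, 594),
    "w388f_ms": (408, 450, 510, 562, 630),
    "cysteine_ms_s": (380, 540, 610),
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclasses.dataclass
class InstrumentSetup:
    """Instrument regime, probe wavelengths, time grid and noise level."""

    regime: str
    wavelengths: tuple[float, ...]
    irf_fwhm: float | None = None          # None → regime default
    time_grid: np.ndarray | None = None    # None → regime default (log-spaced)
    noise_sigma: float = 0.0               # ΔA units, absolute
    excitation_wavelength: float = 470.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        self.wavelengths = tuple(float(w) for w in self.wavelengths)
        if self.irf_fwhm is None:
            self.irf_fwhm = REGIME_IRF_FWHM[self.regime]
        if self.irf_fwhm < 0 or self.noise_sigma < 0:
            raise ValueError("irf_fwhm and noise_sigma must be ≥ 0")
        if self.time_grid is not None:
            self.time_grid = np.asarray(self.time_grid, dtype=float)
            if np.any(np.diff(self.time_grid) <= 0):
                raise ValueError("time grid must be strictly increasing")


@dataclasses.dataclass
class TraceSet:
    """Multi-wavelength ΔA(t) plus the metadata needed to regenerate it."""

    times: np.ndarray               # s
    wavelengths: tuple[float, ...]  # nm
    data: np.ndarray                # (n_times, n_wavelengths), OD units
    setup: InstrumentSetup
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.times.size, len(self.wavelengths)):
            raise ValueError("data shape must be (n_times, n_wavelengths)")

    def column(self, wavelength: float) -> np.ndarray:
        return self.data[:, list(self.wavelengths).index(float(wavelength))]

    def crop(self, t_min: float = -np.inf, t_max: float = np.inf) -> "TraceSet":
        """Restricted copy — e.g. to fit a late-time window."""
        mask = (self.times >= t_min) & (self.times <= t_max)
        return TraceSet(
            times=self.times[mask], wavelengths=self.wavelengths,
            data=self.data[mask], setup=self.setup,
            meta={**self.meta, "cropped": (float(t_min), float(t_max))},
        )


def default_time_grid(regime: str, slowest_tau: float | None = None,
                      n_points: int = 200) -> np.ndarray:
    """Log-spaced default grid for a regime.

    ``ps_ns`` spans 10 ps – 20 ns; ``ns_us`` 1 ns – 80 μs; ``ms_s`` runs
    from 10 μs to five times the scheme's slowest time constant (1 ms when
    unknown) so complete decays are always captured.
    """
    if regime == "ps_ns":
        return np.geomspace(10e-12, 20e-9, n_points)
    if regime == "ns_us":
        return np.geomspace(1e-9, 80e-6, n_points)
    if regime == "ms_s":
        t_max = 5.0 * (slowest_tau if slowest_tau else 1e-3)
        return np.geomspace(10e-6, t_max, max(n_points, 300))
    raise ValueError(f"unknown regime {regime!r}")


# ---------------------------------------------------------------------------
# Analytic IRF convolution
# ---------------------------------------------------------------------------

def gaussian_convolved_decay(times: np.ndarray, rate: float, irf_fwhm: float) -> np.ndarray:
    """θ(t)·exp(−rate·t) convolved with a unit-area Gaussian of given FWHM.

    Evaluated in the overflow-safe erfcx form
    ``½·erfcx((rate·σ − t/σ)/√2)·exp(−t²/2σ²)``; ``rate = 0`` gives the
    convolved step and ``irf_fwhm = 0`` returns the sharp decay exactly.
    """
    t = np.asarray(times, dtype=float)
    if irf_fwhm < 0:
        raise ValueError("irf_fwhm must be ≥ 0")
    if irf_fwhm == 0.0:
        return np.where(t >= 0, np.exp(-rate * np.maximum(t, 0.0)), 0.0)
    sigma = irf_fwhm * _FWHM_TO_SIGMA
    a = (rate * sigma - t / sigma) / np.sqrt(2.0)
    out = np.empty_like(a, dtype=float)
    # erfcx form is exact but overflows for strongly negative a (well past
    # the response, where erfc(a) = 2 to machine precision) — switch there.
    late = a < -25.0
    out[~late] = (0.5 * scipy.special.erfcx(a[~late])
                  * np.exp(-0.5 * (t[~late] / sigma) ** 2))
    if np.any(late):
        # exponent k·(kσ²/2 − t) is strictly negative in this branch
        out[late] = np.exp(rate * (0.5 * rate * sigma**2 - t[late]))
    return out


def convolve_irf(times: np.ndarray, rates: Sequence[float],
                 amplitudes: np.ndarray, irf_fwhm: float) -> np.ndarray:
    """Convolve a multi-exponential model with the instrument response.

    ``amplitudes`` has shape ``(n_rates,)`` or ``(n_rates, n_channels)``;
    returns the summed convolved curve(s).  With ``irf_fwhm = 0`` this is
    the plain multi-exponential (identity convolution).
    """
    amps = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    if amps.shape[0] != len(list(rates)):
        amps = amps.T
    basis = np.column_stack([gaussian_convolved_decay(times, k, irf_fwhm) for k in rates])
    out = basis @ amps
    return out[:, 0] if np.asarray(amplitudes).ndim == 1 else out


# ---------------------------------------------------------------------------
# Beer–Lambert composition
# ---------------------------------------------------------------------------

def state_difference_matrix(scheme: pc.KineticScheme, registry: sp.SpeciesRegistry,
                            wavelengths: Sequence[float]) -> np.ndarray:
    """Δε of every scheme state versus the ground state, (n_states, n_λ)."""
    lam = np.asarray(wavelengths, dtype=float)
    ground = scheme.species[scheme.ground_state]
    eps_ground = sum(registry[s].at(lam) for s in ground)
    rows = []
    for state in scheme.states:
        eps = sum((registry[s].at(lam) for s in scheme.species[state]),
                  np.zeros_like(lam))
        rows.append(eps - eps_ground)
    return np.vstack(rows)


def trace_from_trajectory(traj: pc.PopulationTrajectory,
                          state_species: Mapping[str, Sequence[str]],
                          registry: sp.SpeciesRegistry,
                          pair_concentration: float, path_cm: float,
                          wavelength: float,
                          ground_species: Sequence[str] = pc.GROUND_SPECIES) -> np.ndarray:
    """ΔA(t) at one wavelength from a population trajectory (no IRF).

    ΔA(t) = c·d·Σ_s p_s(t)·Δε_s(λ) with Δε_s the state difference spectrum
    versus the ground state.
    """
    if pair_concentration <= 0:
        raise ValueError("pair_concentration must be positive")
    eps_ground = sum(registry[s].at(wavelength) for s in ground_species)
    delta = np.array([
        sum(registry[s].at(wavelength) for s in state_species[state]) - eps_ground
        for state in traj.states
    ])
    return pair_concentration * path_cm * (traj.populations @ delta)


def noise_sigma_for_fraction(clean_data: np.ndarray, fraction: float) -> float:
    """Absolute noise σ equal to ``fraction`` of the peak |ΔA| of a trace set."""
    return float(fraction * np.max(np.abs(clean_data)))


def _model_components(scheme: pc.KineticScheme, registry: sp.SpeciesRegistry,
                      wavelengths: Sequence[float], concentration: float,
                      path_cm: float):
    """(rates, amplitude matrix (n_modes, n_λ)) of the noiseless ΔA model."""
    rates, weights = pc.exponential_components(scheme)
    delta = state_difference_matrix(scheme, registry, wavelengths)
    amps = concentration * path_cm * scheme.quantum_yield_scaling * (weights @ delta)
    return rates, amps


def generate_dataset(scheme: pc.KineticScheme, setup: InstrumentSetup,
                     registry: sp.SpeciesRegistry | None = None, *,
                     pair_concentration: float = 6.5e-6, path_cm: float = 1.0,
                     eaq_fraction: float = 0.0, tau_eaq: float = 300e-9,
                     noise_fraction: float | None = None) -> TraceSet:
    """Simulate a ΔA trace set for a scheme under an instrument setup.

    The scheme's exact multi-exponential solution is convolved analytically
    with the Gaussian instrument response, scaled by Beer–Lambert with the
    radical-pair concentration (the excited-molecule concentration times the
    scheme's ``quantum_yield_scaling``), optionally augmented with a
    hydrated-electron artifact, and finally overlaid with i.i.d. Gaussian
    noise seeded from ``setup.seed`` — identical seeds give bit-identical
    arrays.  ``noise_fraction`` overrides ``setup.noise_sigma`` with a σ
    equal to that fraction of the peak |ΔA| of the clean data.
    """
    registry = registry if registry is not None else sp.default_registry()
    times = setup.time_grid if setup.time_grid is not None else default_time_grid(
        setup.regime, scheme.slowest_tau())
    rates, amps = _model_components(scheme, registry, setup.wavelengths,
                                    pair_concentration, path_cm)
    clean = convolve_irf(times, rates, amps, setup.irf_fwhm)
    if eaq_fraction:
        if not (0.0 <= eaq_fraction < 1.0):
            raise ValueError("eaq_fraction must be in [0, 1)")
        eps = np.asarray(registry[sp.E_AQ].at(np.asarray(setup.wavelengths, dtype=float)))
        amp = eaq_fraction * pair_concentration * scheme.quantum_yield_scaling * path_cm * eps
        clean = clean + np.outer(gaussian_convolved_decay(times, 1.0 / tau_eaq,
                                                          setup.irf_fwhm), amp)
    sigma = (noise_sigma_for_fraction(clean, noise_fraction)
             if noise_fraction is not None else setup.noise_sigma)
    rng = np.random.default_rng(setup.seed)
    data = clean + rng.normal(0.0, sigma, clean.shape) if sigma > 0 else clean.copy()
    meta = {
        "scheme": scheme.name,
        "pair_concentration_M": pair_concentration,
        "path_cm": path_cm,
        "noise_sigma": sigma,
        "seed": setup.seed,
        "eaq_fraction": eaq_fraction,
        "tau_eaq_s": tau_eaq,
    }
    return TraceSet(times=times, wavelengths=setup.wavelengths, data=data,
                    setup=dataclasses.replace(setup, time_grid=times,
                                              noise_sigma=sigma),
                    meta=meta)


def add_electron_artifact(ts: TraceSet, fraction: float,
                          registry: sp.SpeciesRegistry | None = None,
                          tau_eaq: float = 300e-9) -> TraceSet:
    """Add a hydrated-electron component to an existing trace set.

    The artifact concentration is ``fraction`` of the radical-pair
    concentration recorded in the trace metadata (the convention chosen for
    the "x % hydrated electrons" notation; override the spectrum or τ to
    change it).  e⁻_aq decays with ``tau_eaq``, so on ms–s grids the added
    component has already vanished.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0.0:
        return ts
    registry = registry if registry is not None else sp.default_registry()
    conc = fraction * ts.meta["pair_concentration_M"]
    eps = np.asarray(registry[sp.E_AQ].at(np.asarray(ts.wavelengths, dtype=float)))
    curve = gaussian_convolved_decay(ts.times, 1.0 / tau_eaq, ts.setup.irf_fwhm)
    data = ts.data + np.outer(curve, conc * ts.meta.get("path_cm", 1.0) * eps)
    return TraceSet(times=ts.times, wavelengths=ts.wavelengths, data=data,
                    setup=ts.setup,
                    meta={**ts.meta, "eaq_fraction": fraction, "tau_eaq_s": tau_eaq})
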