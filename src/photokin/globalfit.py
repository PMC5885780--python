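"""Global mono/biexponential fitting of ΔA trace sets.

All wavelengths are fitted simultaneously with shared time constants and
per-wavelength amplitudes (and optional offsets), by unweighted
Levenberg–Marquardt least squares.  The shared lifetimes are the only
nonlinear parameters: for any trial set of τ's the amplitudes are the
solution of a linear least-squares problem, so the fit uses variable
projection — LM iterates on log τ while amplitudes are projected out
exactly at every step.  Initialization is a deterministic multi-start over
a log-spaced τ grid spanning the data, with optional seeded jitter starts.

When an instrument-response FWHM is supplied, the model basis is the
analytic Gaussian-convolved exponential (and a convolved step for the
offset), as appropriate for ps/ns data; otherwise plain exponentials are
fitted and points earlier than 1.5× the recorded IRF FWHM are excluded,
matching the usual practice of fitting post-response windows and
extrapolating amplitudes to t → 0.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
from collections.abc import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .synthgen import TraceSet, gaussian_convolved_decay

__all__ = ["GlobalFitResult", "ModelComparison", "fit_global", "compare_models",
           "amplitude_spectrum"]

IRF_EXCLUSION_FACTOR = 1.5   # drop t < factor × IRF FWHM when not modelling the IRF
MARGINAL_THRESHOLD = 0.05    # default RMSD-improvement threshold for "substantial"


@dataclasses.dataclass
class GlobalFitResult:
    """Shared time constants, per-wavelength amplitudes/offsets, diagnostics."""

    n_components: int
    time_constants: np.ndarray          # s, ascending
    amplitudes: np.ndarray              # (n_wavelengths, n_components)
    offsets: np.ndarray | None          # (n_wavelengths,) or None
    residual_rmsd: float
    stderr_time_constants: np.ndarray   # s (approximate, from the LM Jacobian)
    converged: bool
    iterations: int
    wavelengths: tuple[float, ...]
    irf_fwhm: float | None
    flags: tuple[str, ...] = ()
    _times: np.ndarray | None = dataclasses.field(default=None, repr=False)
    _data: np.ndarray | None = dataclasses.field(default=None, repr=False)

    @property
    def data_fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self._times.tobytes())
        h.update(self._data.tobytes())
        return h.hexdigest()

    def model_matrix(self) -> np.ndarray:
        basis = _basis(self._times, self.time_constants,
                       self.irf_fwhm, self.offsets is not None)
        coeff = self.amplitudes
        if self.offsets is not None:
            coeff = np.column_stack([self.amplitudes, self.offsets])
        return basis @ coeff.T


@dataclasses.dataclass(frozen=True)
class ModelComparison:
    """RMSD-based verdict on whether extra components are warranted."""

    rmsd_ratio: float            # complex / simple
    improvement: float           # 1 − ratio
    extra_parameters: int
    improvement_per_parameter: float
    verdict: str                 # "marginal" or "substantial"


def _basis(times: np.ndarray, taus: Sequence[float], irf_fwhm: float | None,
           offset: bool) -> np.ndarray:
    cols = []
    if irf_fwhm:
        cols = [gaussian_convolved_decay(times, 1.0 / tau, irf_fwhm) for tau in taus]
        if offset:
            cols.append(gaussian_convolved_decay(times, 0.0, irf_fwhm))
    else:
        cols = [np.exp(-times / tau) for tau in taus]
        if offset:
            cols.append(np.ones_like(times))
    return np.column_stack(cols) if cols else np.ones((times.size, 0))


def _project(times, Y, taus, irf_fwhm, offset):
    """Amplitudes/offsets by linear projection; returns (coeffs, residuals)."""
    B = _basis(times, taus, irf_fwhm, offset)
    coeffs, *_ = np.linalg.lstsq(B, Y, rcond=None)
    return coeffs, Y - B @ coeffs


def fit_global(traces: TraceSet, n_components: int, allow_offset: bool = True,
               irf_fwhm: float | None = None, seed: int = 0,
               n_starts: int = 5) -> GlobalFitResult:
    """Global fit with shared lifetimes across all wavelengths of a trace set.

    Parameters
    ----------
    n_components
        1 (mono) or 2 (bi); higher values are accepted but rarely well
        determined on this kind of data.
    allow_offset
        Add a per-wavelength constant (stable residual absorption of
        longer-lived species).
    irf_fwhm
        Fit the Gaussian-convolved model with this response FWHM; ``None``
        fits plain exponentials on the post-response window.
    seed
        Controls the jittered extra initializations only; the fit is
        deterministic given data and seed.

    Non-convergence is reported via ``converged``/``flags`` rather than
    raised; constant (degenerate) data yield a flagged zero-component
    result.
    """
    if n_components < 1:
        raise ValueError("n_components must be ≥ 1")
    times = traces.times
    # canonicalize wavelength order so the fit is exactly invariant under
    # permutations of the input columns (floating-point summation order
    # would otherwise perturb the LM path in the last bits)
    order_wl = np.argsort(np.asarray(traces.wavelengths), kind="stable")
    inverse_wl = np.argsort(order_wl, kind="stable")
    Y = traces.data[:, order_wl]
    Y_orig = traces.data
    if irf_fwhm is None and traces.setup.irf_fwhm:
        mask = times >= IRF_EXCLUSION_FACTOR * traces.setup.irf_fwhm
        times, Y, Y_orig = times[mask], Y[mask], Y_orig[mask]
    n_free = n_components * (1 + len(traces.wavelengths)) + (
        len(traces.wavelengths) if allow_offset else 0)
    if times.size * len(traces.wavelengths) < 2 * n_free:
        raise ValueError("fewer than 2 data points per free parameter")

    scale = float(np.max(np.abs(Y - Y.mean(axis=0)))) if Y.size else 0.0
    if scale < 1e-14:
        return GlobalFitResult(
            n_components=0, time_constants=np.array([]),
            amplitudes=np.zeros((len(traces.wavelengths), 0)),
            offsets=Y_orig.mean(axis=0) if allow_offset else None,
            residual_rmsd=float(np.sqrt(np.mean((Y - Y.mean(axis=0)) ** 2))),
            stderr_time_constants=np.array([]), converged=False, iterations=0,
            wavelengths=traces.wavelengths, irf_fwhm=irf_fwhm,
            flags=("degenerate_constant_data",), _times=times, _data=Y_orig)

    # ---- multi-start initialization over a log-spaced τ grid -------------
    t_lo = max(times[0], 1e-15) if irf_fwhm is None else max(
        times[times > 0][0] if np.any(times > 0) else 1e-15, irf_fwhm / 10)
    t_hi = times[-1]
    grid = np.geomspace(t_lo, t_hi, 7)
    if n_components == 1:
        cand = [(g,) for g in grid]
    else:
        cand = list(itertools.combinations(grid, n_components))
    rng = np.random.default_rng(seed)
    extra = [tuple(np.sort(np.exp(rng.uniform(np.log(t_lo), np.log(t_hi),
                                              n_components)))) for _ in range(2)]
    cand += extra

    def cost(taus) -> float:
        _, R = _project(times, Y, taus, irf_fwhm, allow_offset)
        return float(np.sum(R * R))

    cand.sort(key=cost)
    starts = cand[:n_starts]

    def residual(log_taus):
        _, R = _project(times, Y, np.exp(log_taus), irf_fwhm, allow_offset)
        return R.ravel()

    best = None
    total_nfev = 0
    for start in starts:
        try:
            res = scipy.optimize.least_squares(
                residual, np.log(np.asarray(start)), method="lm",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400 * n_components)
        except Exception:
            continue
        total_nfev += res.nfev
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return GlobalFitResult(
            n_components=n_components, time_constants=np.full(n_components, np.nan),
            amplitudes=np.full((len(traces.wavelengths), n_components), np.nan),
            offsets=None, residual_rmsd=np.nan,
            stderr_time_constants=np.full(n_components, np.nan),
            converged=False, iterations=total_nfev,
            wavelengths=traces.wavelengths, irf_fwhm=irf_fwhm,
            flags=("no_start_converged",), _times=times, _data=Y_orig)

    taus = np.exp(best.x)
    order = np.argsort(taus)
    taus = taus[order]
    coeffs, R = _project(times, Y, taus, irf_fwhm, allow_offset)
    amplitudes = coeffs[:n_components, :].T[inverse_wl]
    offsets = coeffs[n_components, inverse_wl] if allow_offset else None
    rmsd = float(np.sqrt(np.mean(R * R)))

    # approximate τ standard errors from the VP Jacobian on log τ
    n_obs = R.size
    dof = max(n_obs - n_free, 1)
    s2 = 2.0 * best.cost / dof
    try:
        JTJ = best.jac.T @ best.jac
        cov_log = s2 * np.linalg.inv(JTJ)
        stderr = taus * np.sqrt(np.clip(np.diag(cov_log)[order], 0, None))
    except np.linalg.LinAlgError:
        stderr = np.full(n_components, np.nan)

    flags = []
    if not best.success:
        flags.append("lm_not_converged")
    return GlobalFitResult(
        n_components=n_components, time_constants=taus, amplitudes=amplitudes,
        offsets=offsets, residual_rmsd=rmsd, stderr_time_constants=stderr,
        converged=best.success, iterations=total_nfev,
        wavelengths=traces.wavelengths, irf_fwhm=irf_fwhm,
        flags=tuple(flags), _times=times, _data=Y_orig)


def compare_models(fit_simple: GlobalFitResult, fit_complex: GlobalFitResult,
                   threshold: float = MARGINAL_THRESHOLD) -> ModelComparison:
    """Judge whether the richer model improves the fit more than marginally.

    Both fits must be on identical data.  The verdict is "substantial" when
    the RMSD improvement ``1 − rmsd_complex/rmsd_simple`` exceeds
    ``threshold`` (default 5 %), else "marginal".
    """
    if fit_simple.data_fingerprint != fit_complex.data_fingerprint:
        raise ValueError("model comparison requires fits on identical data")
    ratio = (fit_complex.residual_rmsd / fit_simple.residual_rmsd
             if fit_simple.residual_rmsd > 0 else 1.0)
    improvement = 1.0 - ratio
    extra = max(fit_complex.n_components - fit_simple.n_components, 0) * (
        1 + len(fit_simple.wavelengths))
    per_param = improvement / extra if extra else 0.0
    verdict = "substantial" if improvement > threshold else "marginal"
    return ModelComparison(rmsd_ratio=ratio, improvement=improvement,
                           extra_parameters=extra,
                           improvement_per_parameter=per_param, verdict=verdict)


def amplitude_spectrum(fit: GlobalFitResult, component: int | None = None) -> pd.DataFrame:
    """Per-wavelength amplitude table of one component or the t → 0 sum.

    ``component=None`` extrapolates to t = 0 by summing all component
    amplitudes (offsets excluded by definition).
    """
    if not fit.converged and "degenerate_constant_data" in fit.flags:
        raise ValueError("no amplitude spectrum for a degenerate fit")
    if component is None:
        amp = fit.amplitudes.sum(axis=1)
    else:
        if not (0 <= component < fit.n_components):
            raise IndexError(f"component {component} out of range")
        amp = fit.amplitudes[:, component]
    return pd.DataFrame({"wavelength_nm": list(fit.wavelengths), "amplitude": amp})
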