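"""Species assignment of amplitude spectra and actinometric quantum yields.

Two quantitative end points of the analysis live here:

* :func:`decompose_amplitudes` — least-squares decomposition of a fitted
  amplitude spectrum onto candidate radical-pair difference spectra
  (optionally with a hydrated-electron term), ranking singleton candidates
  by residual RMSD.  This is how a kinetic phase is assigned to e.g.
  FAD˙⁻ + Trp˙ rather than FAD˙⁻ + TrpH˙⁺.

* :func:`quantum_yield` — relative actinometry against the
  [Ru(bpy)₃]²⁺ ³MLCT reference (Φ_ref = 1):

      Φ = Φ_ref · [ΔA_s / (Δε_s · f_s)] / [ΔA_ref / (Δε_ref · f_ref)],

  where f = 1 − 10^(−ε₄₇₀·c·d) is the fraction of excitation light
  absorbed over the excitation path d.  Sample and reference are measured
  under the same geometry, so probe-path factors cancel.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import scipy.optimize

from . import spectra as sp

__all__ = ["ActinometryInput", "DecompositionResult", "absorbed_fraction",
           "quantum_yield", "decompose_amplitudes",
           "WT_ACTINOMETRY", "W388F_ACTINOMETRY"]

#: Ru(bpy)₃²⁺ reference constants for 470 nm excitation / 457 nm probing.
RU_DELTA_EPS_457 = -11_000.0     # ³MLCT − ground state at 457 nm
RU_EPS_470 = 10_128.0
RU_CONCENTRATION = 27.4e-6       # M
EXCITATION_PATH_CM = 0.2
RU_PHI = 1.0


@dataclasses.dataclass(frozen=True)
class ActinometryInput:
    """All quantities entering the relative-actinometry quantum yield."""

    dA_sample_457: float
    dA_ref_457: float
    delta_eps_sample_457: float
    c_sample: float                              # M
    eps_sample_470: float
    delta_eps_ref_457: float = RU_DELTA_EPS_457
    eps_ref_470: float = RU_EPS_470
    c_ref: float = RU_CONCENTRATION              # M
    d: float = EXCITATION_PATH_CM                # cm, excitation path
    phi_ref: float = RU_PHI

    def __post_init__(self) -> None:
        for name in ("eps_sample_470", "eps_ref_470", "c_sample", "c_ref", "d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.delta_eps_sample_457 == 0 or self.delta_eps_ref_457 == 0:
            raise ValueError("difference coefficients must be nonzero")


def absorbed_fraction(eps: float, c: float, d: float) -> float:
    """Fraction of excitation light absorbed: 1 − 10^(−ε·c·d), in [0, 1)."""
    if eps < 0 or c < 0 or d < 0:
        raise ValueError("eps, c and d must be ≥ 0")
    return float(1.0 - 10.0 ** (-(eps * c * d)))


def quantum_yield(inp: ActinometryInput) -> float:
    """Quantum yield by relative actinometry (see module docstring).

    Signs follow the convention that a ΔA of the same sign as its Δε gives
    a positive photoproduct concentration; values outside [0, 1.05] emit a
    plausibility warning but are returned unchanged.
    """
    f_s = absorbed_fraction(inp.eps_sample_470, inp.c_sample, inp.d)
    f_r = absorbed_fraction(inp.eps_ref_470, inp.c_ref, inp.d)
    phi = inp.phi_ref * (inp.dA_sample_457 / (inp.delta_eps_sample_457 * f_s)) / (
        inp.dA_ref_457 / (inp.delta_eps_ref_457 * f_r))
    if not (0.0 <= phi <= 1.05):
        warnings.warn(f"quantum yield {phi:.3g} outside the plausible [0, 1] range",
                      stacklevel=2)
    return phi


#: Printed wild-type actinometry inputs (ΔA at 457 nm for sample and Ru
#: reference, FAD˙⁻ + Trp˙ − FAD_ox difference coefficient, concentrations).
WT_ACTINOMETRY = ActinometryInput(
    dA_sample_457=-0.023, dA_ref_457=-0.097,
    delta_eps_sample_457=-3525.0, c_sample=40.0e-6, eps_sample_470=9460.0)

#: Printed W388F inputs (FAD˙⁻ + Tyr˙ − FAD_ox difference coefficient).
W388F_ACTINOMETRY = ActinometryInput(
    dA_sample_457=-0.002, dA_ref_457=-0.108,
    delta_eps_sample_457=-4315.0, c_sample=38.5e-6, eps_sample_470=9460.0)


@dataclasses.dataclass
class DecompositionResult:
    """Joint coefficients plus a singleton-candidate ranking."""

    coefficients: dict[str, float]       # joint fit, concentration·path scale
    residual_rmsd: float                 # of the joint fit
    singleton_rmsd: dict[str, float]     # each candidate (+ e⁻_aq term) alone
    best_candidate: str
    eaq_coefficient: float | None = None
    condition_warning: bool = False

    def ranking(self) -> list[tuple[str, float]]:
        return sorted(self.singleton_rmsd.items(), key=lambda kv: kv[1])


def _design_column(cand, lam: np.ndarray) -> np.ndarray:
    if hasattr(cand, "at"):
        return np.asarray(cand.at(lam), dtype=float)
    return np.asarray(cand(lam), dtype=float)


def _lsq(design: np.ndarray, y: np.ndarray, nonneg: bool):
    if nonneg:
        coef, _ = scipy.optimize.nnls(design, y)
    else:
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(np.sqrt(np.mean(resid**2)))


def decompose_amplitudes(
    wavelengths: Sequence[float],
    amplitudes: Sequence[float],
    candidates: Mapping[str, "sp.DifferenceSpectrum"],
    *,
    include_eaq: bool = False,
    registry: sp.SpeciesRegistry | None = None,
    nonneg: bool = False,
) -> DecompositionResult:
    """Decompose an amplitude spectrum onto candidate difference spectra.

    ``candidates`` maps labels to :class:`~photokin.spectra.DifferenceSpectrum`
    objects (or any callable of wavelength).  The joint least-squares fit
    over all candidates gives concentration-scale coefficients; in addition
    each candidate is fitted alone (plus the hydrated-electron column when
    ``include_eaq``) and ranked by residual RMSD — ``best_candidate`` is the
    singleton with the lowest residual.  Amplitude spectra are signed, so
    coefficients are unconstrained unless ``nonneg`` is set.
    """
    lam = np.asarray(wavelengths, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if lam.size != y.size:
        raise ValueError("wavelengths and amplitudes must have equal length")
    if lam.size < 2:
        raise ValueError("need at least 2 wavelengths")
    if not candidates:
        raise ValueError("need at least one candidate")

    cols = {name: _design_column(c, lam) for name, c in candidates.items()}
    eaq_col = None
    if include_eaq:
        registry = registry if registry is not None else sp.default_registry()
        eaq_col = np.asarray(registry[sp.E_AQ].at(lam), dtype=float)

    names = list(cols)
    design = np.column_stack([cols[n] for n in names]
                             + ([eaq_col] if eaq_col is not None else []))
    condition_warning = False
    if design.shape[1] > 1:
        sv = np.linalg.svd(design, compute_uv=False)
        condition_warning = bool(sv[-1] < 1e-10 * sv[0])
        if condition_warning:
            warnings.warn("candidate difference spectra are nearly collinear at the "
                          "given wavelengths; joint coefficients are ill-determined",
                          stacklevel=2)
    coef, joint_rmsd = _lsq(design, y, nonneg)
    coefficients = dict(zip(names, coef[:len(names)]))
    eaq_coef = float(coef[len(names)]) if eaq_col is not None else None

    singleton_rmsd = {}
    for n in names:
        d1 = np.column_stack([cols[n]] + ([eaq_col] if eaq_col is not None else []))
        _, rmsd1 = _lsq(d1, y, nonneg)
        singleton_rmsd[n] = rmsd1
    best = min(singleton_rmsd, key=singleton_rmsd.get)
    return DecompositionResult(
        coefficients={k: float(v) for k, v in coefficients.items()},
        residual_rmsd=joint_rmsd, singleton_rmsd=singleton_rmsd,
        best_candidate=best, eaq_coefficient=eaq_coef,
        condition_warning=condition_warning)
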