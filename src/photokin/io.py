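"""Readers/writers for the package's plain-text formats and the pipeline.

Formats (all tab-separated or key-value text, bit-exact on round-trip):

* Trace TSV — column ``time_s`` then ``dA_<λ>nm`` per wavelength; ``#``
  header lines carry regime, IRF, seed, scheme id and noise level.
* Spectrum TSV — ``wavelength_nm`` and ``epsilon_M-1cm-1`` columns with the
  species name and anchor provenance in ``#`` headers.
* Scheme config — states with their spectroscopic species and initial
  populations, and transitions as ``from -> to : tau = <value><unit>``.
* Run config (TOML) — scheme, instrument setup, output paths and the seed
  from which all per-stage seeds are derived.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import os
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import globalfit as gf
from . import photocycle as pc
from . import quantify as qt
from . import spectra as sp
from . import synthgen as sg
from .units import format_time, parse_time

__all__ = [
    "read_trace_tsv", "write_trace_tsv",
    "read_spectrum_tsv", "write_spectrum_tsv",
    "read_scheme_config", "write_scheme_config",
    "read_actinometry_config",
    "RunConfig", "read_run_config", "write_run_config",
    "stage_seed", "run_pipeline", "write_fit_report",
]

_FLOAT_FMT = "%.17g"  # shortest-lossless is not guaranteed; 17 s.f. is


class FormatError(ValueError):
    """A file does not conform to one of the package's text dialects."""


def _fmt(x: float) -> str:
    return _FLOAT_FMT % float(x)


# ---------------------------------------------------------------------------
# Trace TSV
# ---------------------------------------------------------------------------

_TRACE_MAGIC = "# photokin-traces v1"

_TRACE_META_FIELDS = (
    ("regime", str), ("irf_fwhm_s", float), ("seed", int), ("scheme", str),
    ("noise_sigma", float), ("pair_concentration_M", float), ("path_cm", float),
    ("excitation_nm", float),
)


def write_trace_tsv(ts: sg.TraceSet, path: str | os.PathLike) -> None:
    lines = [_TRACE_MAGIC]
    values = {
        "regime": ts.setup.regime,
        "irf_fwhm_s": ts.setup.irf_fwhm,
        "seed": ts.setup.seed,
        "scheme": ts.meta.get("scheme", "unknown"),
        "noise_sigma": ts.meta.get("noise_sigma", 0.0),
        "pair_concentration_M": ts.meta.get("pair_concentration_M", 0.0),
        "path_cm": ts.meta.get("path_cm", 1.0),
        "excitation_nm": ts.setup.excitation_wavelength,
    }
    for key, kind in _TRACE_META_FIELDS:
        v = values[key]
        lines.append(f"# {key} = {v if kind is not float else _fmt(v)}")
    for extra in ts.meta.get("extra_comments", ()):
        lines.append(f"# {extra}")
    header = ["time_s"] + [f"dA_{w:g}nm" for w in ts.wavelengths]
    lines.append("\t".join(header))
    for i, t in enumerate(ts.times):
        lines.append("\t".join([_fmt(t)] + [_fmt(v) for v in ts.data[i]]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace_tsv(path: str | os.PathLike) -> sg.TraceSet:
    text = Path(path).read_text()
    meta_raw: dict[str, str] = {}
    extra: list[str] = []
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.startswith("photokin-traces"):
                continue
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta_raw[k.strip()] = v.strip()
            else:
                extra.append(stripped)
        elif line.strip():
            body.append(line)
    if not body:
        raise FormatError(f"{path}: no data rows")
    try:
        df = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t",
                         float_precision="round_trip")
    except Exception as exc:  # pandas reports the offending line number
        raise FormatError(f"{path}: malformed table: {exc}") from exc
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing required column 'time_s'")
    wl_cols = [c for c in df.columns if c.startswith("dA_")]
    if not wl_cols:
        raise FormatError(f"{path}: no dA_<wavelength>nm columns")
    try:
        wavelengths = tuple(float(c[len("dA_"):-len("nm")]) for c in wl_cols)
    except ValueError as exc:
        raise FormatError(f"{path}: bad wavelength column name") from exc
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # +header +1-based
        raise FormatError(f"{path}: malformed row at data line {bad}")
    setup = sg.InstrumentSetup(
        regime=meta_raw.get("regime", "ns_us"),
        wavelengths=wavelengths,
        irf_fwhm=float(meta_raw.get("irf_fwhm_s", 0.0)),
        time_grid=df["time_s"].to_numpy(),
        noise_sigma=float(meta_raw.get("noise_sigma", 0.0)),
        excitation_wavelength=float(meta_raw.get("excitation_nm", 470.0)),
        seed=int(meta_raw.get("seed", 0)),
    )
    meta = {
        "scheme": meta_raw.get("scheme", "unknown"),
        "noise_sigma": float(meta_raw.get("noise_sigma", 0.0)),
        "pair_concentration_M": float(meta_raw.get("pair_concentration_M", 0.0)),
        "path_cm": float(meta_raw.get("path_cm", 1.0)),
        "seed": int(meta_raw.get("seed", 0)),
    }
    if extra:
        meta["extra_comments"] = tuple(extra)
    return sg.TraceSet(times=df["time_s"].to_numpy(), wavelengths=wavelengths,
                       data=df[wl_cols].to_numpy(), setup=setup, meta=meta)


# ---------------------------------------------------------------------------
# Spectrum TSV
# ---------------------------------------------------------------------------

def write_spectrum_tsv(table: sp.SpectrumTable, path: str | os.PathLike) -> None:
    lines = ["# photokin-spectrum v1", f"# species = {table.species_name}"]
    for a in table.anchors:
        lines.append(f"# anchor = {_fmt(a.wavelength)} {_fmt(a.epsilon)} {a.provenance}")
    lines.append("wavelength_nm\tepsilon_M-1cm-1")
    for w, e in zip(table.wavelengths, table.epsilon):
        lines.append(f"{_fmt(w)}\t{_fmt(e)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum_tsv(path: str | os.PathLike) -> sp.SpectrumTable:
    text = Path(path).read_text()
    species = Path(path).stem
    anchors: list[sp.Anchor] = []
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.startswith("species"):
                species = stripped.split("=", 1)[1].strip()
            elif stripped.startswith("anchor"):
                parts = stripped.split("=", 1)[1].strip().split(None, 2)
                anchors.append(sp.Anchor(float(parts[0]), float(parts[1]),
                                         parts[2] if len(parts) > 2 else ""))
        elif line.strip():
            body.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t",
                     float_precision="round_trip")
    if "wavelength_nm" not in df.columns or "epsilon_M-1cm-1" not in df.columns:
        raise FormatError(f"{path}: expected wavelength_nm and epsilon_M-1cm-1 columns")
    return sp.SpectrumTable(species_name=species,
                            wavelengths=df["wavelength_nm"].to_numpy(),
                            epsilon=df["epsilon_M-1cm-1"].to_numpy(),
                            anchors=tuple(anchors))


# ---------------------------------------------------------------------------
# Scheme config
# ---------------------------------------------------------------------------

def write_scheme_config(scheme: pc.KineticScheme, path: str | os.PathLike) -> None:
    lines = ["# photokin-scheme v1",
             f"name = {scheme.name}",
             f"quantum_yield_scaling = {_fmt(scheme.quantum_yield_scaling)}",
             f"ground_state = {scheme.ground_state}",
             "", "[states]"]
    for state, p0 in zip(scheme.states, scheme.initial_population):
        species = " + ".join(scheme.species[state]) or "-"
        lines.append(f"{state} : {species} : p0 = {_fmt(p0)}")
    lines.append("")
    lines.append("[transitions]")
    for t in scheme.transitions:
        lines.append(f"{t.source} -> {t.target} : tau = {format_time(t.tau, 's')}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scheme_config(path: str | os.PathLike) -> pc.KineticScheme:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scheme file not found: {path}")
    name = path.stem
    qys = 1.0
    ground = "ground"
    states: list[str] = []
    species: dict[str, tuple[str, ...]] = {}
    p0: list[float] = []
    transitions: list[pc.Transition] = []
    section = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            section = line.strip("[]").strip().lower()
            continue
        try:
            if section is None:
                key, value = (s.strip() for s in line.split("=", 1))
                if key == "name":
                    name = value
                elif key == "quantum_yield_scaling":
                    qys = float(value)
                elif key == "ground_state":
                    ground = value
                else:
                    raise FormatError(f"unknown key {key!r}")
            elif section == "states":
                state_part, species_part, p0_part = (s.strip() for s in line.split(":"))
                states.append(state_part)
                sp_names = tuple(s.strip() for s in species_part.split("+")) \
                    if species_part != "-" else ()
                species[state_part] = sp_names
                p0.append(float(p0_part.split("=", 1)[1]))
            elif section == "transitions":
                arrow, tau_part = (s.strip() for s in line.split(":", 1))
                src, dst = (s.strip() for s in arrow.split("->"))
                tau = parse_time(tau_part.split("=", 1)[1].strip())
                transitions.append(pc.Transition(src, dst, 1.0 / tau))
            else:
                raise FormatError(f"unknown section [{section}]")
        except FormatError:
            raise
        except Exception as exc:
            raise FormatError(f"{path}:{lineno}: cannot parse {raw!r}: {exc}") from exc
    return pc.KineticScheme(
        name=name, states=tuple(states), species=species,
        transitions=tuple(transitions), initial_population=np.array(p0),
        quantum_yield_scaling=qys, ground_state=ground)


def resolve_scheme(ref: str, cysteine_molar: float = 0.0) -> pc.KineticScheme:
    """Preset name or scheme-config path → KineticScheme."""
    if ref in pc.PRESET_VARIANTS:
        return pc.preset_scheme(ref, cysteine_molar=cysteine_molar)
    return read_scheme_config(ref)


# ---------------------------------------------------------------------------
# Actinometry config (flat key-value text)
# ---------------------------------------------------------------------------

def read_actinometry_config(path: str | os.PathLike) -> qt.ActinometryInput:
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            key, value = (s.strip() for s in line.split("=", 1))
            values[key] = float(value)
        except Exception as exc:
            raise FormatError(f"{path}:{lineno}: cannot parse {raw!r}") from exc
    try:
        return qt.ActinometryInput(**values)
    except TypeError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Fit report
# ---------------------------------------------------------------------------

def write_fit_report(fit: gf.GlobalFitResult, path: str | os.PathLike) -> None:
    lines = ["# photokin-fit v1",
             f"n_components = {fit.n_components}",
             f"converged = {fit.converged}",
             f"iterations = {fit.iterations}",
             f"residual_rmsd = {_fmt(fit.residual_rmsd)}",
             f"flags = {','.join(fit.flags) or '-'}"]
    for i, (tau, se) in enumerate(zip(fit.time_constants, fit.stderr_time_constants)):
        lines.append(f"tau_{i} = {format_time(tau, 's')}")
        lines.append(f"tau_{i}_stderr = {format_time(se, 's') if np.isfinite(se) else 'nan'}")
    for j, w in enumerate(fit.wavelengths):
        amps = " ".join(_fmt(a) for a in fit.amplitudes[j])
        lines.append(f"amplitudes_{w:g}nm = {amps or '-'}")
        if fit.offsets is not None:
            lines.append(f"offset_{w:g}nm = {_fmt(fit.offsets[j])}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Run config and pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Fully serializable description of an end-to-end pipeline run."""

    scheme: str = "WT"                      # preset name or scheme file path
    regime: str = "ms_s"
    wavelengths: tuple[float, ...] = sg.PROBE_WAVELENGTHS["wt_ms"]
    noise_fraction: float = 0.01
    n_components: int = 2
    allow_offset: bool = True
    fit_irf: bool = False                   # use the convolved model in the fit
    pair_concentration: float = 6.5e-6
    path_cm: float = 1.0
    cysteine_molar: float = 0.0
    eaq_fraction: float = 0.0
    seed: int = 0
    outdir: str = "photokin_run"
    verbosity: int = 1

    def to_toml(self) -> str:
        def fmt(v):
            if isinstance(v, bool):
                return "true" if v else "false"
            if isinstance(v, (int,)):
                return str(v)
            if isinstance(v, float):
                return _fmt(v)
            if isinstance(v, str):
                return f'"{v}"'
            if isinstance(v, tuple):
                return "[" + ", ".join(fmt(x) for x in v) + "]"
            raise TypeError(type(v))
        lines = ["# photokin run configuration"]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {fmt(getattr(self, f.name))}")
        return "\n".join(lines) + "\n"


def write_run_config(config: RunConfig, path: str | os.PathLike) -> None:
    Path(path).write_text(config.to_toml())


def read_run_config(path: str | os.PathLike) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "wavelengths" in raw:
        raw["wavelengths"] = tuple(float(w) for w in raw["wavelengths"])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed.

    SHA-256 of ``"<seed>/<stage>"`` reduced mod 2³¹ — stable across
    platforms and Python versions, and documented so partial reruns can
    reproduce any stage in isolation.
    """
    digest = hashlib.sha256(f"{seed}/{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


_CANDIDATE_SETS = {
    "default": (
        ((sp.FAD_ANION, sp.TRP_NEUTRAL), (sp.FAD_OX,)),
        ((sp.FAD_ANION, sp.TRPH_CATION), (sp.FAD_OX,)),
        ((sp.FAD_ANION, sp.TYR_NEUTRAL), (sp.FAD_OX,)),
    ),
}


def run_pipeline(config: RunConfig,
                 actinometry: qt.ActinometryInput | None = None) -> dict:
    """simulate → fit → decompose (→ quantum yield), writing a report bundle.

    Writes trace TSV, fit report, decomposition table and a summary that
    compares recovered time constants with the generating scheme's values.
    Each stage failure is isolated: prior outputs are kept and the failing
    stage is named in the raised error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"outdir": str(outdir)}

    stage = "simulate"
    try:
        scheme = resolve_scheme(config.scheme, config.cysteine_molar)
        registry = sp.default_registry()
        setup = sg.InstrumentSetup(
            regime=config.regime, wavelengths=config.wavelengths,
            seed=stage_seed(config.seed, "simulate"))
        ts = sg.generate_dataset(
            scheme, setup, registry,
            pair_concentration=config.pair_concentration, path_cm=config.path_cm,
            eaq_fraction=config.eaq_fraction, noise_fraction=config.noise_fraction)
        write_trace_tsv(ts, outdir / "traces.tsv")
        results["traces"] = str(outdir / "traces.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    stage = "fit"
    try:
        fit = gf.fit_global(
            ts, n_components=config.n_components, allow_offset=config.allow_offset,
            irf_fwhm=ts.setup.irf_fwhm if config.fit_irf else None,
            seed=stage_seed(config.seed, "fit"))
        write_fit_report(fit, outdir / "fit_report.txt")
        results["fit"] = fit
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    stage = "decompose"
    try:
        spec_df = gf.amplitude_spectrum(fit)
        candidates = {
            "+".join(f): sp.difference_spectrum(f, d, registry)
            for f, d in _CANDIDATE_SETS["default"]
        }
        dec = qt.decompose_amplitudes(
            spec_df["wavelength_nm"], spec_df["amplitude"], candidates)
        dec_lines = ["# photokin-decomposition v1",
                     f"best_candidate = {dec.best_candidate}"]
        for name, rmsd in dec.ranking():
            dec_lines.append(f"rmsd[{name}] = {_fmt(rmsd)}")
        (outdir / "decomposition.txt").write_text("\n".join(dec_lines) + "\n")
        results["decomposition"] = dec
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    stage = "quantum_yield"
    if actinometry is not None:
        try:
            results["quantum_yield"] = qt.quantum_yield(actinometry)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # summary: recovered constants vs the scheme's observable eigen-constants
    rates, _ = pc.exponential_components(scheme)
    gen_taus = np.sort(1.0 / rates[rates > 0])
    lines = ["# photokin-summary v1",
             f"scheme = {scheme.name}", f"regime = {config.regime}",
             f"seed = {config.seed}",
             "generating_taus_s = " + " ".join(_fmt(t) for t in gen_taus),
             "recovered_taus_s = " + " ".join(_fmt(t) for t in fit.time_constants)]
    for tau in fit.time_constants:
        nearest = gen_taus[np.argmin(np.abs(np.log(gen_taus / tau)))]
        lines.append(f"recovered {format_time(tau, None, 6)} vs nearest generating "
                     f"{format_time(nearest, None, 6)} "
                     f"(ratio {_fmt(tau / nearest)})")
    if "quantum_yield" in results:
        lines.append(f"quantum_yield = {_fmt(results['quantum_yield'])}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    results["summary"] = str(outdir / "summary.txt")
    return results
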