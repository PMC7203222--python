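"""Synthetic EEM datasets with the structure the analysis pipeline assumes.

Each sample is a tri-linear mixture: a handful of fluorophores, each a rank-1
Gaussian excitation x emission profile, scaled by a per-sample concentration
drawn log-uniformly.  On top of the clean signal the generator layers the
artefacts the pre-processing chain exists to remove:

* first- and second-order Rayleigh scatter ridges — additive Gaussian bands
  along ``em = ex`` and ``em = 2*ex``, roughly 10x brighter than the
  fluorophore signal and with a random per-sample amplitude (scatter in real
  cultures is dominated by elastic scattering off cells and water and is not
  proportional to analyte content);
* inner-filter attenuation — every cell multiplied by
  ``10**(-(A(ex)+A(em))/2)``, the exact inverse of the correction applied
  downstream, using a per-sample absorbance spectrum built from Gaussian
  component absorption bands;
* additive Gaussian detector noise.

Responses are log-linear in the component concentrations (``intercept +
sum coef_c * log10(conc_c) + noise``), mirroring how biological responses
are modelled on a log10 scale downstream.

Default fluorophores mimic an algal culture: a chlorophyll-like pigment
(ex 440/40 nm, em 683/12 nm), a protein-like fluorophore from aromatic amino
acids (ex 280/12, em 340/25), and an accessory pigment (ex 490/30,
em 660/20).  Gaussian shapes are an analytic simplification — real pigment
spectra are multi-peaked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .eem_data import (
    EEM,
    AbsorbanceSpectrum,
    EEMDataset,
    ManifestRecord,
    ResponseTable,
    WavelengthGrid,
    write_absorbance,
    write_eem,
    write_manifest,
    write_response_table,
)

__all__ = [
    "FluorophoreSpec",
    "ResponseModel",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "component_profile",
    "attenuate_inner_filter",
    "simulate_dataset",
    "write_bundle",
]

# acquisition grids of a typical benchtop spectrofluorometer scan
DEFAULT_EX_GRID = WavelengthGrid(250.0, 790.0, 5.0)
DEFAULT_EM_GRID = WavelengthGrid(260.0, 800.0, 5.0)


@dataclass(frozen=True)
class FluorophoreSpec:
    """A rank-1 Gaussian fluorophore with an associated absorption band.

    ``brightness`` is peak intensity per concentration unit;
    ``absorptivity`` is peak absorbance per concentration unit (1 cm path),
    with the absorption band Gaussian in wavelength around ``ex_mean``.
    """

    name: str
    ex_mean: float
    ex_sd: float
    em_mean: float
    em_sd: float
    brightness: float = 1000.0
    absorptivity: float = 0.05
    absorption_sd: float | None = None  # defaults to ex_sd

    def __post_init__(self) -> None:
        if self.em_mean <= self.ex_mean:
            raise ValueError(f"{self.name}: Stokes shift requires em_mean > ex_mean")
        if self.ex_sd <= 0 or self.em_sd <= 0:
            raise ValueError(f"{self.name}: spectral widths must be positive")


DEFAULT_FLUOROPHORES = (
    FluorophoreSpec("pigment", ex_mean=440, ex_sd=40, em_mean=683, em_sd=12,
                    brightness=1000.0, absorptivity=0.05),
    FluorophoreSpec("protein", ex_mean=280, ex_sd=12, em_mean=340, em_sd=25,
                    brightness=600.0, absorptivity=0.04),
    FluorophoreSpec("accessory", ex_mean=490, ex_sd=30, em_mean=660, em_sd=20,
                    brightness=400.0, absorptivity=0.03),
)


@dataclass(frozen=True)
class ResponseModel:
    """Ground-truth response: intercept + sum coef_c*log10(conc_c) + noise."""

    name: str = "response"
    intercept: float = 6.0
    coefficients: tuple[float, ...] = (1.0, 0.0, 0.0)
    noise_sd: float = 0.02


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Concentrations are log-uniform within ``conc_bounds`` (default 1-3, the
    ~3-fold within-run variation typical of a batch cultivation).  ``snr`` is
    the ratio of the median per-sample peak clean intensity to the additive
    noise standard deviation; ``snr=inf`` disables noise.  Scatter amplitudes
    are peak ridge intensities before the per-sample x U(0.5, 1.5) jitter.
    """

    ex_grid: WavelengthGrid = DEFAULT_EX_GRID
    em_grid: WavelengthGrid = DEFAULT_EM_GRID
    fluorophores: tuple[FluorophoreSpec, ...] = DEFAULT_FLUOROPHORES
    n_samples: int = 60
    conc_bounds: tuple[tuple[float, float], ...] | None = None  # per component; default (1,3)
    scatter_amplitude_first: float = 10000.0
    scatter_amplitude_second: float = 10000.0
    scatter_sd: float = 8.0
    apply_ife: bool = True
    snr: float = 50.0
    response: ResponseModel = field(default_factory=ResponseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive (use inf for noiseless)")
        if len(self.response.coefficients) != len(self.fluorophores):
            raise ValueError("one response coefficient per fluorophore required")
        bounds = self.bounds()
        for lo, hi in bounds:
            if lo <= 0 or hi <= lo:
                raise ValueError("concentration bounds must satisfy 0 < lo < hi")

    def bounds(self) -> tuple[tuple[float, float], ...]:
        if self.conc_bounds is None:
            return tuple((1.0, 3.0) for _ in self.fluorophores)
        if len(self.conc_bounds) != len(self.fluorophores):
            raise ValueError("one concentration bound pair per fluorophore required")
        return self.conc_bounds


@dataclass
class GroundTruth:
    concentrations: np.ndarray  # (n, C)
    clean_tensor: np.ndarray  # (n, J, K), fluorophore signal only
    scatter_tensor: np.ndarray  # (n, J, K), additive scatter ridges
    true_response: np.ndarray  # (n,) before noise
    component_names: list[str]


@dataclass
class SimulatedStudy:
    """In-memory equivalent of a manifest: EEMs + absorbance + responses + truth."""

    eems: list[EEM]
    absorbance: list[AbsorbanceSpectrum]
    responses: ResponseTable
    truth: GroundTruth
    config: SimulationConfig

    def dataset(self) -> EEMDataset:
        from .eem_data import assemble_dataset

        return assemble_dataset(self.eems)


def _gauss(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mean) / sd) ** 2)


def component_profile(
    spec: FluorophoreSpec, ex_grid: WavelengthGrid, em_grid: WavelengthGrid
) -> np.ndarray:
    """Rank-1 [em x ex] profile: outer product of peak-normalised Gaussians."""
    em_prof = _gauss(em_grid.values, spec.em_mean, spec.em_sd)
    ex_prof = _gauss(ex_grid.values, spec.ex_mean, spec.ex_sd)
    return spec.brightness * np.outer(em_prof, ex_prof)


def attenuate_inner_filter(
    matrix: np.ndarray,
    spec: AbsorbanceSpectrum,
    ex_grid: WavelengthGrid,
    em_grid: WavelengthGrid,
) -> np.ndarray:
    """Apply inner-filter attenuation: multiply by ``10**(-(A(ex)+A(em))/2)``.

    Exact inverse of the downstream correction when the same absorbance
    spectrum is supplied.
    """
    from .eem_data import interpolate_absorbance

    a_ex = np.asarray(interpolate_absorbance(spec, ex_grid.values))
    a_em = np.asarray(interpolate_absorbance(spec, em_grid.values))
    return matrix * 10.0 ** (-(a_em[:, None] + a_ex[None, :]) / 2.0)


def _scatter_ridges(
    ex: np.ndarray, em: np.ndarray, amp1: float, amp2: float, sd: float
) -> tuple[np.ndarray, np.ndarray]:
    diff1 = em[:, None] - ex[None, :]
    diff2 = em[:, None] - 2.0 * ex[None, :]
    return amp1 * np.exp(-0.5 * (diff1 / sd) ** 2), amp2 * np.exp(-0.5 * (diff2 / sd) ** 2)


def simulate_dataset(config: SimulationConfig) -> SimulatedStudy:
    """Draw one synthetic study under ``config`` (fully seeded)."""
    rng = np.random.default_rng(config.seed)
    ex, em = config.ex_grid.values, config.em_grid.values
    J, K = em.size, ex.size
    n, C = config.n_samples, len(config.fluorophores)

    bounds = config.bounds()
    log_lo = np.log10([b[0] for b in bounds])
    log_hi = np.log10([b[1] for b in bounds])
    conc = 10.0 ** (log_lo + (log_hi - log_lo) * rng.random((n, C)))

    profiles = np.stack(
        [component_profile(f, config.ex_grid, config.em_grid) for f in config.fluorophores]
    )  # (C, J, K)
    clean = np.einsum("ic,cjk->ijk", conc, profiles)

    ridge1, ridge2 = _scatter_ridges(
        ex, em, config.scatter_amplitude_first, config.scatter_amplitude_second,
        config.scatter_sd,
    )
    jitter1 = rng.uniform(0.5, 1.5, size=n)
    jitter2 = rng.uniform(0.5, 1.5, size=n)
    scatter = jitter1[:, None, None] * ridge1 + jitter2[:, None, None] * ridge2
    if config.scatter_amplitude_first == 0 and config.scatter_amplitude_second == 0:
        scatter = np.zeros_like(clean)

    if np.isfinite(config.snr):
        noise_sd = float(np.median(clean.max(axis=(1, 2)))) / config.snr
        noise = rng.normal(0.0, noise_sd, size=clean.shape)
    else:
        noise = np.zeros_like(clean)

    # per-sample absorbance on a grid covering both excitation and emission ranges
    wl_lo = min(config.ex_grid.start, config.em_grid.start)
    wl_hi = max(config.ex_grid.stop, config.em_grid.stop)
    abs_wl = np.arange(wl_lo, wl_hi + 1e-9, config.ex_grid.step)
    abs_bands = np.stack(
        [
            f.absorptivity * _gauss(abs_wl, f.ex_mean, f.absorption_sd or f.ex_sd)
            for f in config.fluorophores
        ]
    )  # (C, W)
    absorbance_curves = conc @ abs_bands  # (n, W)

    eems: list[EEM] = []
    specs: list[AbsorbanceSpectrum] = []
    raw = clean + scatter + noise
    for i in range(n):
        sid = f"synthetic_{i:03d}"
        spec = AbsorbanceSpectrum(sid, abs_wl.copy(), absorbance_curves[i])
        intensity = (
            attenuate_inner_filter(raw[i], spec, config.ex_grid, config.em_grid)
            if config.apply_ife
            else raw[i].copy()
        )
        eems.append(
            EEM(sample_id=sid, ex_grid=config.ex_grid, em_grid=config.em_grid,
                intensity=intensity)
        )
        specs.append(spec)

    coefs = np.asarray(config.response.coefficients, dtype=float)
    true_response = config.response.intercept + np.log10(conc) @ coefs
    observed = true_response + (
        rng.normal(0.0, config.response.noise_sd, size=n)
        if config.response.noise_sd > 0
        else 0.0
    )
    responses = ResponseTable(
        data=pd.DataFrame(
            {config.response.name: observed}, index=[e.sample_id for e in eems]
        ),
        log10_applied={config.response.name: True},
    )
    truth = GroundTruth(
        concentrations=conc,
        clean_tensor=clean,
        scatter_tensor=scatter,
        true_response=true_response,
        component_names=[f.name for f in config.fluorophores],
    )
    return SimulatedStudy(eems=eems, absorbance=specs, responses=responses,
                          truth=truth, config=config)


def write_bundle(study: SimulatedStudy, out_dir: str | Path) -> Path:
    """Write a full CSV bundle: EEM grids, absorbance, responses, manifest, truth."""
    out = Path(out_dir)
    (out / "eems").mkdir(parents=True, exist_ok=True)
    (out / "absorbance").mkdir(exist_ok=True)
    records = []
    for eem, spec in zip(study.eems, study.absorbance):
        eem_path = f"eems/{eem.sample_id}.csv"
        abs_path = f"absorbance/{eem.sample_id}.csv"
        write_eem(eem, out / eem_path)
        write_absorbance(spec, out / abs_path)
        records.append(
            ManifestRecord(sample_id=eem.sample_id, eem_path=eem_path,
                           absorbance_path=abs_path)
        )
    write_manifest(records, out / "manifest.json")
    write_response_table(study.responses, out / "responses.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "component_names": study.truth.component_names,
                "concentrations": study.truth.concentrations.tolist(),
                "true_response": study.truth.true_response.tolist(),
                "seed": study.config.seed,
            },
            fh,
        )
    return out
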