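"""Domain types and CSV readers/writers for excitation-emission matrix (EEM) data.

An EEM is a fluorescence landscape: emitted intensity over a rectangular grid of
emission (rows) x excitation (columns) wavelengths.  Missing cells (e.g. the
excised first-order Rayleigh band) are tracked with an explicit boolean mask so
that a legitimate zero intensity is never conflated with "no data"; internally
the intensity array carries NaN at masked cells.

CSV dialects
------------
* EEM grid: cell (1,1) blank or ``em\\ex``; first row = excitation wavelengths
  ascending; first column = emission wavelengths ascending; body = intensities;
  blank cells = missing.
* Absorbance: two columns, header ``wavelength_nm,absorbance``.
* Responses: ``sample_id`` plus one column per measured variable; blank = not
  measured.
* Manifest: JSON array of ``{sample_id, eem_path, absorbance_path, metadata}``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "EEM",
    "AbsorbanceSpectrum",
    "EEMDataset",
    "ResponseTable",
    "ManifestRecord",
    "read_eem",
    "write_eem",
    "read_absorbance",
    "write_absorbance",
    "interpolate_absorbance",
    "assemble_dataset",
    "read_response_table",
    "write_response_table",
    "read_manifest",
    "write_manifest",
    "EEMFormatError",
    "GridError",
]

RESPONSE_COLUMNS = (
    "cell_concentration",
    "chlorophyll",
    "fa_total",
    "fa_saturated",
    "fa_unsaturated",
)


class EEMFormatError(ValueError):
    """Raised when an EEM/absorbance file does not follow the documented dialect."""


class GridError(ValueError):
    """Raised for non-uniform or otherwise invalid wavelength grids."""


@dataclass(frozen=True)
class WavelengthGrid:
    """A uniform, strictly increasing wavelength grid in nanometres."""

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise GridError(f"step must be positive, got {self.step}")
        if self.stop <= self.start:
            raise GridError(f"stop must exceed start ({self.start}..{self.stop})")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise GridError(
                f"(stop - start)/step must be an integer: ({self.stop} - {self.start})/{self.step}"
            )

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "WavelengthGrid":
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise GridError("grid needs at least two wavelengths")
        diffs = np.diff(arr)
        if np.any(diffs <= 0):
            raise GridError("wavelengths must be strictly increasing")
        step = diffs[0]
        if not np.allclose(diffs, step, rtol=0, atol=1e-6):
            raise GridError("wavelength spacing is not uniform")
        return cls(start=float(arr[0]), stop=float(arr[-1]), step=float(step))


def _masked_intensity(intensity: np.ndarray, missing: np.ndarray) -> np.ndarray:
    out = np.array(intensity, dtype=float)
    out[missing] = np.nan
    return out


@dataclass
class EEM:
    """One sample's excitation-emission matrix.

    ``intensity`` is oriented [emission rows x excitation columns]; masked cells
    hold NaN and are flagged in ``missing``.
    """

    sample_id: str
    ex_grid: WavelengthGrid
    em_grid: WavelengthGrid
    intensity: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        expected = (len(self.em_grid), len(self.ex_grid))
        if self.intensity.shape != expected:
            raise GridError(
                f"intensity shape {self.intensity.shape} does not match grids {expected}"
            )
        if self.missing is None:
            self.missing = ~np.isfinite(self.intensity)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != expected:
            raise GridError("missing mask shape does not match grids")
        if not np.all(np.isfinite(self.intensity[~self.missing])):
            raise ValueError(f"{self.sample_id}: non-finite intensity outside mask")
        self.intensity = _masked_intensity(self.intensity, self.missing)

    def copy(self) -> "EEM":
        return EEM(
            sample_id=self.sample_id,
            ex_grid=self.ex_grid,
            em_grid=self.em_grid,
            intensity=self.intensity.copy(),
            missing=self.missing.copy(),
        )


@dataclass
class AbsorbanceSpectrum:
    """A sample's absorbance spectrum, 1 cm path length assumed."""

    sample_id: str
    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and absorbance must be 1-D and equal length")
        if self.wavelengths.size == 0:
            raise ValueError("empty absorbance spectrum")
        order = np.argsort(self.wavelengths)
        self.wavelengths = self.wavelengths[order]
        self.absorbance = self.absorbance[order]
        if np.any(np.diff(self.wavelengths) == 0):
            raise ValueError(f"{self.sample_id}: duplicate wavelengths")
        if np.any(self.absorbance < 0):
            raise ValueError(
                f"{self.sample_id}: negative absorbance; clip or reject at read time"
            )


@dataclass
class EEMDataset:
    """A stack of EEMs on shared grids: tensor [sample x emission x excitation]."""

    samples: list[str]
    ex_grid: WavelengthGrid
    em_grid: WavelengthGrid
    tensor: np.ndarray
    global_missing: np.ndarray

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        expected = (len(self.samples), len(self.em_grid), len(self.ex_grid))
        if self.tensor.shape != expected:
            raise GridError(f"tensor shape {self.tensor.shape} != {expected}")
        self.global_missing = np.asarray(self.global_missing, dtype=bool)

    def __len__(self) -> int:
        return len(self.samples)

    def eem(self, i: int) -> EEM:
        """Slice sample ``i`` back out as an EEM."""
        return EEM(
            sample_id=self.samples[i],
            ex_grid=self.ex_grid,
            em_grid=self.em_grid,
            intensity=self.tensor[i].copy(),
        )

    def subset(self, indices: Sequence[int]) -> "EEMDataset":
        idx = list(indices)
        sub = self.tensor[idx]
        return EEMDataset(
            samples=[self.samples[i] for i in idx],
            ex_grid=self.ex_grid,
            em_grid=self.em_grid,
            tensor=sub,
            global_missing=~np.all(np.isfinite(sub), axis=0),
        )


@dataclass
class ResponseTable:
    """Per-sample measured responses with an explicit log10 bookkeeping flag.

    ``data`` is indexed by sample_id; NaN marks "not measured".  ``log10_applied``
    records, per column, whether the stored values are on the log10 scale.
    """

    data: pd.DataFrame
    units: Mapping[str, str] = field(default_factory=dict)
    log10_applied: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        for col in self.data.columns:
            self.log10_applied.setdefault(col, False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def values_for(self, column: str) -> tuple[list[str], np.ndarray]:
        """Sample ids and values for one variable, dropping unmeasured samples."""
        col = self.data[column].dropna()
        return list(col.index), col.to_numpy(dtype=float)


@dataclass
class ManifestRecord:
    sample_id: str
    eem_path: str
    absorbance_path: str | None = None
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_eem(path: str | Path) -> EEM:
    """Read an EEM CSV grid (see module docstring for the dialect)."""
    path = Path(path)
    raw = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=False)
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise EEMFormatError(f"{path}: EEM grid needs a header row and column")
    try:
        ex_values = raw.iloc[0, 1:].astype(float).to_numpy()
        em_values = raw.iloc[1:, 0].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise EEMFormatError(f"{path}: malformed wavelength header: {exc}") from None
    try:
        ex_grid = WavelengthGrid.from_values(ex_values)
        em_grid = WavelengthGrid.from_values(em_values)
    except GridError as exc:
        raise GridError(f"{path}: {exc}") from None
    body = raw.iloc[1:, 1:].to_numpy()
    intensity = np.full(body.shape, np.nan)
    for (i, j), cell in np.ndenumerate(body):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            continue
        text = str(cell).strip()
        if text == "":
            continue
        try:
            intensity[i, j] = float(text)
        except ValueError:
            continue  # non-numeric cell -> missing
    return EEM(sample_id=path.stem, ex_grid=ex_grid, em_grid=em_grid, intensity=intensity)


def write_eem(eem: EEM, path: str | Path) -> None:
    """Write an EEM back to the CSV grid dialect; missing cells become blank."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("em\\ex," + ",".join(f"{v:g}" for v in eem.ex_grid.values) + "\n")
        for i, em in enumerate(eem.em_grid.values):
            cells = [
                "" if eem.missing[i, j] else repr(float(eem.intensity[i, j]))
                for j in range(len(eem.ex_grid))
            ]
            fh.write(f"{em:g}," + ",".join(cells) + "\n")


def read_absorbance(
    path: str | Path, negative_policy: str = "clip"
) -> AbsorbanceSpectrum:
    """Read a 2-column absorbance CSV.

    Negative readings (baseline noise) are clipped to 0 by default; pass
    ``negative_policy="reject"`` to raise instead.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise EEMFormatError(f"{path}: expected 2 columns (wavelength_nm, absorbance)")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    ab = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(ab < 0):
        if negative_policy == "reject":
            raise ValueError(f"{path}: negative absorbance values")
        ab = np.clip(ab, 0.0, None)
    return AbsorbanceSpectrum(sample_id=path.stem, wavelengths=wl, absorbance=ab)


def write_absorbance(spec: AbsorbanceSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths, "absorbance": spec.absorbance}
    ).to_csv(path, index=False)


def interpolate_absorbance(spec: AbsorbanceSpectrum, wavelength) -> np.ndarray | float:
    """Linearly interpolate absorbance at ``wavelength`` (scalar or array, nm).

    Wavelengths outside the measured range return 0 with a warning: the
    long-wavelength absorbance of dilute cultures is negligible.
    """
    wl = np.asarray(wavelength, dtype=float)
    out = np.interp(wl, spec.wavelengths, spec.absorbance)
    outside = (wl < spec.wavelengths[0]) | (wl > spec.wavelengths[-1])
    if np.any(outside):
        warnings.warn(
            f"{spec.sample_id}: absorbance requested outside measured range "
            f"[{spec.wavelengths[0]:g}, {spec.wavelengths[-1]:g}] nm; using 0",
            stacklevel=2,
        )
        out = np.where(outside, 0.0, out)
    return float(out) if np.isscalar(wavelength) else out


def assemble_dataset(eems: Iterable[EEM]) -> EEMDataset:
    """Stack EEMs sharing identical grids into a three-way dataset.

    ``global_missing`` is the union of per-sample masks, so a cell is modelled
    only if every sample measured it.
    """
    eems = list(eems)
    if not eems:
        raise ValueError("assemble_dataset needs at least one EEM")
    ref = eems[0]
    for e in eems[1:]:
        if e.ex_grid != ref.ex_grid or e.em_grid != ref.em_grid:
            raise GridError(f"sample {e.sample_id!r}: grid differs from {ref.sample_id!r}")
    tensor = np.stack([e.intensity for e in eems])
    global_missing = np.any(np.stack([e.missing for e in eems]), axis=0)
    return EEMDataset(
        samples=[e.sample_id for e in eems],
        ex_grid=ref.ex_grid,
        em_grid=ref.em_grid,
        tensor=tensor,
        global_missing=global_missing,
    )


def read_response_table(path: str | Path) -> ResponseTable:
    df = pd.read_csv(path, index_col="sample_id")
    df.index = df.index.astype(str)
    return ResponseTable(data=df)


def write_response_table(table: ResponseTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="sample_id")


def read_manifest(path: str | Path, check_exists: bool = True) -> list[ManifestRecord]:
    path = Path(path)
    with open(path) as fh:
        records = json.load(fh)
    out = []
    seen: set[str] = set()
    for rec in records:
        r = ManifestRecord(
            sample_id=str(rec["sample_id"]),
            eem_path=rec["eem_path"],
            absorbance_path=rec.get("absorbance_path"),
            metadata=rec.get("metadata", {}),
        )
        if r.sample_id in seen:
            raise ValueError(f"duplicate sample_id {r.sample_id!r} in manifest")
        seen.add(r.sample_id)
        if check_exists:
            base = path.parent
            for p in (r.eem_path, r.absorbance_path):
                if p is not None and not (base / p).exists():
                    raise FileNotFoundError(f"manifest references missing file {p!r}")
        out.append(r)
    return out


def write_manifest(records: Sequence[ManifestRecord], path: str | Path) -> None:
    payload = [
        {
            "sample_id": r.sample_id,
            "eem_path": r.eem_path,
            "absorbance_path": r.absorbance_path,
            "metadata": r.metadata,
        }
        for r in records
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
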