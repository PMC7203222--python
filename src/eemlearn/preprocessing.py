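"""Scatter and inner-filter pre-processing for EEMs.

The chain applied to each sample, in a fixed configurable order:

1. inner-filter effect (IFE) correction — every cell multiplied by
   ``10**((A(ex) + A(em)) / 2)`` where ``A`` is the sample's absorbance
   (the standard absorbance-based correction for re-absorption at high
   optical density);
2. first-order Rayleigh excision — cells within a band ``|em - ex| <=
   halfwidth`` become missing (the elastic-scatter ridge carries no
   fluorophore information and is not proportional to analyte content);
3. second-order Rayleigh interpolation — cells within ``|em - 2*ex| <=
   halfwidth`` are replaced by 1-D linear interpolation along the emission
   axis between the nearest non-missing neighbours outside the band;
4. sub-diagonal zeroing — cells with ``em < ex`` (emission bluer than the
   exciting light, physically empty) are set to 0 and marked present.

IFE is applied first because the correction is multiplicative on measured
intensities and the scatter interpolation should operate on corrected values;
the order is configurable via ``PreprocessConfig.order``.

Band halfwidths default to +/-15 nm for both Rayleigh orders (common drEEM
practice); they are not dictated by physics and are exposed in the config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .eem_data import (
    EEM,
    AbsorbanceSpectrum,
    EEMDataset,
    ManifestRecord,
    assemble_dataset,
    interpolate_absorbance,
    read_absorbance,
    read_eem,
)

__all__ = [
    "PreprocessConfig",
    "correct_inner_filter",
    "excise_first_order_rayleigh",
    "interpolate_second_order_rayleigh",
    "zero_below_diagonal",
    "preprocess_sample",
    "preprocess_samples",
    "preprocess_dataset",
    "EEMPreprocessor",
]

logger = logging.getLogger(__name__)

DEFAULT_ORDER = ("ife", "rayleigh1", "rayleigh2", "zero_subdiagonal")


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the pre-processing chain.

    Parameters
    ----------
    first_order_halfwidth, second_order_halfwidth : float, nm
        Half-width of the excised / interpolated Rayleigh bands. Band
        membership is decided per cell, so non-multiples of the grid step
        are allowed.
    apply_ife : bool
        Whether to apply the inner-filter correction at all.
    ife_absorbance_threshold : float
        If the sample's maximum absorbance does not exceed this value the
        EEM is returned unchanged (absorption too weak to matter). The
        default 0 applies the correction whenever any absorbance is present.
    order : tuple of stage names
        Execution order over {"ife", "rayleigh1", "rayleigh2",
        "zero_subdiagonal"}.
    """

    first_order_halfwidth: float = 15.0
    second_order_halfwidth: float = 15.0
    apply_ife: bool = True
    ife_absorbance_threshold: float = 0.0
    order: tuple[str, ...] = DEFAULT_ORDER

    def __post_init__(self) -> None:
        if self.first_order_halfwidth < 0 or self.second_order_halfwidth < 0:
            raise ValueError("halfwidths must be >= 0")
        unknown = set(self.order) - set(DEFAULT_ORDER)
        if unknown:
            raise ValueError(f"unknown preprocessing stages: {sorted(unknown)}")


def correct_inner_filter(
    eem: EEM, spec: AbsorbanceSpectrum | None, config: PreprocessConfig | None = None
) -> EEM:
    """Multiply every non-missing cell by ``10**((A(ex)+A(em))/2)``.

    Returns the EEM unchanged when the correction is disabled, when no
    spectrum is supplied with ``apply_ife=False``, or when ``max(A)`` does
    not exceed ``ife_absorbance_threshold``.
    """
    config = config or PreprocessConfig()
    if not config.apply_ife:
        return eem.copy()
    if spec is None:
        raise ValueError(f"{eem.sample_id}: IFE correction requested without absorbance")
    if float(np.max(spec.absorbance)) <= config.ife_absorbance_threshold:
        return eem.copy()
    a_ex = np.asarray(interpolate_absorbance(spec, eem.ex_grid.values))
    a_em = np.asarray(interpolate_absorbance(spec, eem.em_grid.values))
    factor = 10.0 ** ((a_em[:, None] + a_ex[None, :]) / 2.0)
    out = eem.copy()
    out.intensity = np.where(out.missing, np.nan, out.intensity * factor)
    return out


def excise_first_order_rayleigh(eem: EEM, halfwidth: float = 15.0) -> EEM:
    """Mark cells with ``|em - ex| <= halfwidth`` as missing."""
    ex = eem.ex_grid.values[None, :]
    em = eem.em_grid.values[:, None]
    band = np.abs(em - ex) <= halfwidth
    out = eem.copy()
    out.missing = out.missing | band
    out.intensity[band] = np.nan
    return out


def interpolate_second_order_rayleigh(eem: EEM, halfwidth: float = 15.0) -> EEM:
    """Replace the ``|em - 2*ex| <= halfwidth`` band by emission-axis interpolation.

    Per excitation column, band cells are rebuilt by linear interpolation in
    emission wavelength between the nearest non-missing cells outside the
    band.  Where a flanking neighbour does not exist (band touches the grid
    edge or everything on that side is missing) the band cells become missing.
    """
    out = eem.copy()
    em = eem.em_grid.values
    for j, ex in enumerate(eem.ex_grid.values):
        band = np.abs(em - 2.0 * ex) <= halfwidth
        if not band.any():
            continue
        lo_candidates = np.where((em < 2.0 * ex - halfwidth) & ~out.missing[:, j])[0]
        hi_candidates = np.where((em > 2.0 * ex + halfwidth) & ~out.missing[:, j])[0]
        rows = np.where(band)[0]
        if lo_candidates.size == 0 or hi_candidates.size == 0:
            out.missing[rows, j] = True
            out.intensity[rows, j] = np.nan
            continue
        lo, hi = lo_candidates[-1], hi_candidates[0]
        frac = (em[rows] - em[lo]) / (em[hi] - em[lo])
        out.intensity[rows, j] = (1 - frac) * out.intensity[lo, j] + frac * out.intensity[hi, j]
        out.missing[rows, j] = False
    return out


def zero_below_diagonal(eem: EEM) -> EEM:
    """Zero cells with ``em < ex`` (strictly) and mark them present.

    Emission bluer than the exciting light is physically empty; zeroing wins
    over a prior scatter excision in the overlapping wedge so the final
    spectra carry an explicit zeroed lower triangle.
    """
    ex = eem.ex_grid.values[None, :]
    em = eem.em_grid.values[:, None]
    below = em < ex
    out = eem.copy()
    out.intensity[below] = 0.0
    out.missing[below] = False
    return out


_STAGES = {
    "ife": lambda eem, spec, cfg: correct_inner_filter(eem, spec, cfg),
    "rayleigh1": lambda eem, spec, cfg: excise_first_order_rayleigh(
        eem, cfg.first_order_halfwidth
    ),
    "rayleigh2": lambda eem, spec, cfg: interpolate_second_order_rayleigh(
        eem, cfg.second_order_halfwidth
    ),
    "zero_subdiagonal": lambda eem, spec, cfg: zero_below_diagonal(eem),
}


def preprocess_sample(
    eem: EEM,
    spec: AbsorbanceSpectrum | None = None,
    config: PreprocessConfig | None = None,
) -> EEM:
    """Run the full pre-processing chain on one sample in ``config.order``."""
    config = config or PreprocessConfig()
    out = eem
    for stage in config.order:
        before_missing = int(out.missing.sum())
        out = _STAGES[stage](out, spec, config)
        logger.debug(
            "%s: stage %s, missing %d -> %d",
            eem.sample_id,
            stage,
            before_missing,
            int(out.missing.sum()),
        )
    return out


def preprocess_samples(
    eems: Sequence[EEM],
    specs: Sequence[AbsorbanceSpectrum | None] | None = None,
    config: PreprocessConfig | None = None,
) -> EEMDataset:
    """Pre-process each sample, then stack into an EEMDataset."""
    config = config or PreprocessConfig()
    if specs is None:
        specs = [None] * len(eems)
    if len(specs) != len(eems):
        raise ValueError("one absorbance spectrum (or None) per EEM required")
    processed = []
    for eem, spec in zip(eems, specs):
        try:
            processed.append(preprocess_sample(eem, spec, config))
        except Exception as exc:
            raise RuntimeError(f"pre-processing failed for sample {eem.sample_id!r}: {exc}") from exc
    ds = assemble_dataset(processed)
    logger.info(
        "pre-processed %d samples: %d of %d cells globally missing",
        len(processed),
        int(ds.global_missing.sum()),
        ds.global_missing.size,
    )
    return ds


def preprocess_dataset(
    manifest: Iterable[ManifestRecord],
    config: PreprocessConfig | None = None,
    base_dir: str | Path = ".",
) -> EEMDataset:
    """Load every manifest record from disk and pre-process the set together."""
    manifest = list(manifest)
    if not manifest:
        raise ValueError("empty manifest")
    base = Path(base_dir)
    eems, specs = [], []
    for rec in manifest:
        eem = read_eem(base / rec.eem_path)
        eem.sample_id = rec.sample_id
        spec = (
            read_absorbance(base / rec.absorbance_path)
            if rec.absorbance_path is not None
            else None
        )
        if spec is not None:
            spec.sample_id = rec.sample_id
        eems.append(eem)
        specs.append(spec)
    return preprocess_samples(eems, specs, config)


class EEMPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer wrapping the pre-processing chain.

    ``transform`` accepts a sequence of EEMs (paired with ``absorbance`` passed
    at construction or fit time) and returns an :class:`EEMDataset`.
    """

    def __init__(
        self,
        first_order_halfwidth: float = 15.0,
        second_order_halfwidth: float = 15.0,
        apply_ife: bool = True,
        ife_absorbance_threshold: float = 0.0,
        order: tuple[str, ...] = DEFAULT_ORDER,
    ):
        self.first_order_halfwidth = first_order_halfwidth
        self.second_order_halfwidth = second_order_halfwidth
        self.apply_ife = apply_ife
        self.ife_absorbance_threshold = ife_absorbance_threshold
        self.order = order

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            first_order_halfwidth=self.first_order_halfwidth,
            second_order_halfwidth=self.second_order_halfwidth,
            apply_ife=self.apply_ife,
            ife_absorbance_threshold=self.ife_absorbance_threshold,
            order=tuple(self.order),
        )

    def fit(self, X=None, y=None):  # stateless
        return self

    def transform(
        self, X: Sequence[EEM], absorbance: Sequence[AbsorbanceSpectrum | None] | None = None
    ) -> EEMDataset:
        return preprocess_samples(X, absorbance, self._config())
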