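"""Peak-list data model, MGF/TSV I/O, significance filtering, external
recalibration against reference masses, and tolerance-based peak matching."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .masscalc import InputError

__all__ = [
    "Peak",
    "Spectrum",
    "MatchTolerance",
    "CalibrationModel",
    "PeakMatch",
    "FormatError",
    "read_peaklist",
    "write_peaklist",
    "filter_significant",
    "recalibrate",
    "match_peaks",
    "MS1_WINDOW",
]

#: MS1 acquisition window (Da): positive-ion reflectron mode, m/z 500-4000.
MS1_WINDOW = (500.0, 4000.0)

# peaks closer than this are considered the same centroid and merged
_MERGE_EPS = 1e-6


class FormatError(ValueError):
    """Malformed peak-list file."""


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise FormatError(f"non-positive m/z: {self.mz}")
        if self.intensity < 0:
            raise FormatError(f"negative intensity at m/z {self.mz}")


@dataclass(frozen=True)
class MatchTolerance:
    """Absolute symmetric m/z matching window in Da (the +-0.2 Da practice of
    TOF/TOF peak assignment; ppm tolerances are not used)."""

    window: float = 0.2

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise InputError("tolerance window must be positive")


@dataclass(frozen=True)
class CalibrationModel:
    """Affine external-calibration model: corrected = slope * observed + offset."""

    slope: float
    offset: float
    n_anchors: int

    def __post_init__(self) -> None:
        if not (0.9 < self.slope < 1.1):
            raise InputError(f"calibration slope {self.slope} outside (0.9, 1.1)")
        if self.n_anchors < 1:
            raise InputError("calibration requires at least one anchor")

    def apply(self, mz: float) -> float:
        return self.slope * mz + self.offset


@dataclass(frozen=True)
class Spectrum:
    """An ordered centroided peak list.

    Peaks are stored strictly sorted by m/z with near-duplicate centroids
    merged by intensity summation. MS/MS spectra carry the declared singly
    protonated precursor (``precursor_mh``). ``metadata`` records provenance
    details such as the noise level used by significance filtering.
    """

    peaks: tuple[Peak, ...]
    ms_level: int = 1
    precursor_mh: Optional[float] = None
    source: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ms_level not in (1, 2):
            raise InputError(f"ms_level must be 1 or 2, got {self.ms_level}")
        peaks = sorted(self.peaks, key=lambda p: p.mz)
        merged: list[Peak] = []
        warned = False
        for p in peaks:
            if merged and abs(p.mz - merged[-1].mz) < _MERGE_EPS:
                if not warned:
                    warnings.warn(
                        f"duplicate m/z centroids merged in {self.source or 'spectrum'}",
                        stacklevel=2,
                    )
                    warned = True
                prev = merged.pop()
                merged.append(Peak(prev.mz, prev.intensity + p.intensity))
            else:
                merged.append(p)
        object.__setattr__(self, "peaks", tuple(merged))
        if self.ms_level == 2:
            if self.precursor_mh is None:
                raise InputError("MS/MS spectrum requires precursor_mh")
            if self.peaks and self.precursor_mh < self.peaks[-1].mz - 1.0:
                raise InputError(
                    "precursor_mh below highest fragment m/z: "
                    f"{self.precursor_mh} < {self.peaks[-1].mz} - 1.0"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    @property
    def total_ion_current(self) -> float:
        return float(sum(p.intensity for p in self.peaks))


def _spectrum_from_arrays(mz, intensity, **kw) -> Spectrum:
    return Spectrum(
        peaks=tuple(Peak(float(m), float(i)) for m, i in zip(mz, intensity)), **kw
    )


def read_peaklist(
    source,
    format: str = "tsv",
    ms_level: int = 1,
    precursor_mh: Optional[float] = None,
) -> list[Spectrum]:
    """Read centroided peak lists from MGF or two-column TSV.

    MGF blocks become MS/MS spectra with PEPMASS mapped to ``precursor_mh``.
    A TSV file (header ``mz<TAB>intensity``) yields a single spectrum at the
    given ``ms_level`` (``precursor_mh`` must then be supplied for level 2).
    An empty file yields an empty list.
    """
    path = Path(source)
    if format == "mgf":
        spectra = []
        with _mgf.MGF(str(path)) as reader:
            for entry in reader:
                params = entry.get("params", {})
                pep = params.get("pepmass")
                pmh = float(pep[0]) if pep is not None else None
                spectra.append(
                    _spectrum_from_arrays(
                        entry["m/z array"],
                        entry["intensity array"],
                        ms_level=2,
                        precursor_mh=pmh,
                        source=str(params.get("title", path.name)),
                    )
                )
        return spectra
    if format == "tsv":
        rows = []
        text = path.read_text().strip()
        if not text:
            return []
        lines = text.splitlines()
        start = 1 if lines[0].lower().replace(" ", "").startswith("mz") else 0
        for ln in lines[start:]:
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if len(parts) < 2:
                raise FormatError(f"expected two tab-separated columns: {ln!r}")
            rows.append((float(parts[0]), float(parts[1])))
        if not rows:
            return []
        spec = _spectrum_from_arrays(
            [r[0] for r in rows],
            [r[1] for r in rows],
            ms_level=ms_level,
            precursor_mh=precursor_mh,
            source=path.name,
        )
        return [spec]
    raise InputError(f"unknown peak-list format: {format!r}")


def write_peaklist(spectra: Sequence[Spectrum] | Spectrum, path, format: str = "tsv") -> None:
    """Write spectra as MGF or TSV; m/z is emitted with six decimals."""
    if isinstance(spectra, Spectrum):
        spectra = [spectra]
    path = Path(path)
    if format == "tsv":
        if len(spectra) > 1:
            raise InputError("TSV holds a single spectrum per file")
        with open(path, "w") as fh:
            fh.write("mz\tintensity\n")
            for p in spectra[0].peaks:
                fh.write(f"{p.mz:.6f}\t{p.intensity:.6f}\n")
        return
    if format == "mgf":
        entries = []
        for spec in spectra:
            entries.append(
                {
                    "m/z array": spec.mz,
                    "intensity array": spec.intensity,
                    "params": {
                        "title": spec.source or "spectrum",
                        "pepmass": spec.precursor_mh or 0.0,
                        "charge": "1+",
                    },
                }
            )
        _mgf.write(entries, output=str(path), file_mode="w")
        return
    raise InputError(f"unknown peak-list format: {format!r}")


def filter_significant(spectrum: Spectrum, noise_factor: float = 2.0) -> Spectrum:
    """Keep peaks at least ``noise_factor`` times the baseline noise.

    Baseline noise is estimated as the median peak intensity of the centroided
    list — robust to the few intense true peaks a single-cell spectrum carries.
    The noise value used is recorded in the result's metadata so the filter can
    be reproduced; an empty spectrum passes through empty.
    """
    if noise_factor <= 0:
        raise InputError("noise_factor must be positive")
    if not spectrum.peaks:
        return spectrum
    noise = float(np.median(spectrum.intensity))
    threshold = noise_factor * noise
    kept = tuple(p for p in spectrum.peaks if p.intensity >= threshold)
    meta = dict(spectrum.metadata)
    meta.update(noise_level=noise, noise_factor=noise_factor)
    return replace(spectrum, peaks=kept, metadata=meta)


def recalibrate(
    spectrum: Spectrum,
    reference: Sequence[float],
    tol: MatchTolerance = MatchTolerance(),
) -> tuple[Spectrum, Optional[CalibrationModel]]:
    """Externally recalibrate against known reference masses.

    Each reference m/z is matched to the nearest observed peak within the
    tolerance window. One anchor gives a constant-offset model; two or more
    give a least-squares affine model (corrected = slope * observed + offset).
    If no reference matches, the spectrum is returned unchanged with ``None``
    in place of the model.
    """
    if not reference:
        raise InputError("at least one reference mass is required")
    anchors: list[tuple[float, float]] = []  # (observed, expected)
    for match in match_peaks(spectrum, list(reference), tol):
        if match.peak is not None:
            anchors.append((match.peak.mz, match.target))
    if not anchors:
        return spectrum, None
    if len(anchors) == 1:
        slope, offset = 1.0, anchors[0][1] - anchors[0][0]
    else:
        obs = np.array([a[0] for a in anchors])
        exp = np.array([a[1] for a in anchors])
        slope, offset = np.polyfit(obs, exp, 1)
    model = CalibrationModel(float(slope), float(offset), len(anchors))
    corrected = tuple(Peak(model.apply(p.mz), p.intensity) for p in spectrum.peaks)
    meta = dict(spectrum.metadata)
    meta["calibration"] = (model.slope, model.offset, model.n_anchors)
    return replace(spectrum, peaks=corrected, metadata=meta), model


@dataclass(frozen=True)
class PeakMatch:
    """The outcome of matching one target m/z against a spectrum."""

    target: float
    peak: Optional[Peak]
    error: Optional[float]  # observed - target, Da
    shared: bool = False  # the matched peak also serves another target


def match_peaks(
    spectrum: Spectrum,
    targets: Sequence[float],
    tol: MatchTolerance = MatchTolerance(),
) -> list[PeakMatch]:
    """Match each target m/z to the nearest observed peak within the window.

    Ties on distance are broken toward higher intensity, then lower m/z. One
    peak may serve multiple targets; such matches are flagged ``shared``.
    """
    if len(targets) == 0:
        raise InputError("targets must be non-empty")
    results: list[PeakMatch] = []
    mzs = spectrum.mz
    for t in targets:
        best: Optional[Peak] = None
        if len(mzs):
            lo = np.searchsorted(mzs, t - tol.window)
            hi = np.searchsorted(mzs, t + tol.window, side="right")
            for p in spectrum.peaks[lo:hi]:
                if best is None:
                    best = p
                    continue
                d_new, d_best = abs(p.mz - t), abs(best.mz - t)
                if d_new < d_best - 1e-12:
                    best = p
                elif abs(d_new - d_best) <= 1e-12 and (
                    p.intensity > best.intensity
                    or (p.intensity == best.intensity and p.mz < best.mz)
                ):
                    best = p
        if best is None:
            results.append(PeakMatch(t, None, None))
        else:
            results.append(PeakMatch(t, best, best.mz - t))
    used: dict[float, int] = {}
    for r in results:
        if r.peak is not None:
            used[r.peak.mz] = used.get(r.peak.mz, 0) + 1
    return [
        replace(r, shared=r.peak is not None and used[r.peak.mz] > 1) for r in results
    ]
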