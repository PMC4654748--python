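"""Synthetic-data generators emulating single-cell MALDI-TOF/TOF inputs.

Real single-neuron spectra are not quantitative (ion suppression, shot-to-shot
variability), so the generators model only the features the identification
pipeline consumes: which theoretical ions appear, small m/z jitter, uniform
chemical-noise peaks, phosphocholine/choline contaminant peaks, an affine
calibration distortion, and MS1 satellite peaks (glycine-extended processing
intermediates, +16/+32 oxidation adducts). Precursor proteins are emulated as
a signal region followed by a dibasic-flanked, C-terminally glycine-extended
peptide cassette.

All generators are pure functions of (inputs, seed): the same seed and
configuration give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotate import CHOLINE_MZ, PC_MZ
from .masscalc import (
    CTerm,
    InputError,
    IonType,
    Peptide,
    fragment_ions,
    peptide_mh,
)
from .precursor import PrecursorProtein
from .spectra import MS1_WINDOW, Peak, Spectrum

__all__ = [
    "SimConfig",
    "PC_MZ",
    "CHOLINE_MZ",
    "simulate_msms",
    "simulate_ms1",
    "simulate_precursor",
]

#: Relative base intensities per ion type: y > b > a > internal > immonium is
#: the typical TOF/TOF ordering for small peptides.
_DEFAULT_BASE_INTENSITY: Mapping[IonType, float] = MappingProxyType(
    {
        IonType.y: 100.0,
        IonType.b: 80.0,
        IonType.a: 30.0,
        IonType.internal_b: 20.0,
        IonType.immonium: 25.0,
        IonType.precursor: 50.0,
        IonType.precursor_loss: 60.0,
    }
)

#: Per-ion-type detection probabilities; spectra carry "nearly the full set"
#: of b/y ions while satellites appear less reliably.
_DEFAULT_DETECTION: Mapping[IonType, float] = MappingProxyType(
    {
        IonType.y: 0.95,
        IonType.b: 0.9,
        IonType.a: 0.6,
        IonType.internal_b: 0.5,
        IonType.immonium: 0.6,
        IonType.precursor: 0.8,
        IonType.precursor_loss: 0.9,
    }
)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults describe a well-behaved acquisition.

    ``detection_prob`` maps ion types to per-ion Bernoulli detection
    probabilities; ``mz_jitter_sd`` is the Gaussian centroid error in Da;
    ``n_noise_peaks`` uniform chemical-noise peaks are drawn over
    ``noise_mz_range`` (defaulting to 100 Da up to the precursor for MS/MS);
    ``intensity_sd`` is the sigma of the multiplicative lognormal intensity
    noise; ``calibration`` is an affine (slope, offset) distortion applied
    last; the MS1 adduct fractions set satellite intensities relative to the
    parent peak.
    """

    seed: int = 0
    detection_prob: Mapping[IonType, float] = field(
        default_factory=lambda: _DEFAULT_DETECTION
    )
    mz_jitter_sd: float = 0.02
    n_noise_peaks: int = 20
    noise_mz_range: Optional[tuple[float, float]] = None
    base_intensity: Mapping[IonType, float] = field(
        default_factory=lambda: _DEFAULT_BASE_INTENSITY
    )
    intensity_sd: float = 0.5
    noise_intensity: float = 8.0
    contaminants: bool = False
    calibration: tuple[float, float] = (1.0, 0.0)
    glycine_extended_fraction: float = 0.3
    ox16_fraction: float = 0.05
    ox32_fraction: float = 0.02
    ion_types: frozenset = frozenset(
        {
            IonType.a,
            IonType.b,
            IonType.y,
            IonType.internal_b,
            IonType.immonium,
            IonType.precursor_loss,
        }
    )

    def __post_init__(self) -> None:
        for p in self.detection_prob.values():
            if not 0.0 <= p <= 1.0:
                raise InputError("detection probabilities must lie in [0, 1]")
        if self.mz_jitter_sd < 0 or self.n_noise_peaks < 0:
            raise InputError("jitter sd and noise-peak count must be non-negative")


def _rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng(config.seed)


def _finalize(
    entries: list[tuple[float, float]],
    config: SimConfig,
    rng: np.random.Generator,
    ms_level: int,
    precursor_mh: Optional[float],
    source: str,
    noise_range: tuple[float, float],
) -> Spectrum:
    """Add noise peaks and contaminants, apply calibration distortion, build."""
    for _ in range(config.n_noise_peaks):
        mz = rng.uniform(*noise_range)
        inten = config.noise_intensity * rng.lognormal(0.0, config.intensity_sd)
        entries.append((mz, inten))
    if config.contaminants:
        for cmz, scale in ((PC_MZ, 8.0), (CHOLINE_MZ, 4.0)):
            mz = cmz + (rng.normal(0.0, config.mz_jitter_sd) if config.mz_jitter_sd else 0.0)
            entries.append((mz, config.noise_intensity * scale))
    slope, offset = config.calibration
    entries = [(slope * mz + offset, inten) for mz, inten in entries]
    peaks = tuple(Peak(mz, inten) for mz, inten in sorted(entries) if mz > 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # near-coincident draws merge silently
        return Spectrum(
            peaks,
            ms_level=ms_level,
            precursor_mh=precursor_mh,
            source=source,
            metadata={"simulated": True, "seed": config.seed},
        )


def simulate_msms(peptide: Peptide, config: SimConfig = SimConfig()) -> Spectrum:
    """Simulate a singly protonated MALDI MS/MS spectrum of a peptide.

    Each theoretical ion is drawn with its detection probability, jittered in
    m/z, and given a lognormal intensity around its ion-type base level; noise
    peaks, optional contaminants, and the calibration distortion are applied
    on top. The declared ``precursor_mh`` is recorded before distortion.
    """
    rng = _rng(config)
    mh = peptide_mh(peptide)
    ions = fragment_ions(peptide, config.ion_types)
    entries: list[tuple[float, float]] = []
    for ion in sorted(ions, key=lambda i: (i.ion_type.value, i.span)):
        p = config.detection_prob.get(ion.ion_type, 1.0)
        detected = True if p >= 1.0 else rng.random() < p
        jitter = rng.normal(0.0, config.mz_jitter_sd) if config.mz_jitter_sd else 0.0
        inten = config.base_intensity.get(ion.ion_type, 10.0) * (
            rng.lognormal(0.0, config.intensity_sd) if config.intensity_sd else 1.0
        )
        if detected and ion.mz > 0:
            entries.append((ion.mz + jitter, inten))
    noise_range = config.noise_mz_range or (100.0, mh)
    return _finalize(
        entries, config, rng, 2, mh, f"simulated MS/MS {peptide.sequence}", noise_range
    )


def simulate_ms1(
    peptides: Sequence[Peptide], config: SimConfig = SimConfig()
) -> Spectrum:
    """Simulate a single-cell MS1 spectrum over the 500-4000 Da window.

    Each peptide contributes its MH+ peak plus satellites: the
    glycine-extended processing intermediate (+58.005, for amidated peptides)
    and +16/+32 oxidation adducts, with intensities set by the configured
    fractions of the parent intensity. Peptides outside the acquisition
    window are omitted with a warning.
    """
    rng = _rng(config)
    lo, hi = MS1_WINDOW
    entries: list[tuple[float, float]] = []
    for peptide in peptides:
        mh = peptide_mh(peptide)
        if not lo <= mh <= hi:
            warnings.warn(
                f"peptide {peptide.sequence} MH+ {mh:.2f} outside MS1 window, omitted",
                stacklevel=2,
            )
            continue
        base = 100.0 * (
            rng.lognormal(0.0, config.intensity_sd) if config.intensity_sd else 1.0
        )
        satellites = [(mh, base)]
        if config.glycine_extended_fraction > 0 and peptide.c_term is CTerm.amide:
            satellites.append((mh + 58.00548, base * config.glycine_extended_fraction))
        if config.ox16_fraction > 0:
            satellites.append((mh + 15.99491, base * config.ox16_fraction))
        if config.ox32_fraction > 0:
            satellites.append((mh + 31.98983, base * config.ox32_fraction))
        for mz, inten in satellites:
            jitter = rng.normal(0.0, config.mz_jitter_sd) if config.mz_jitter_sd else 0.0
            if lo <= mz <= hi:
                entries.append((mz + jitter, inten))
    noise_range = config.noise_mz_range or MS1_WINDOW
    return _finalize(entries, config, rng, 1, None, "simulated MS1", noise_range)


# flanking regions avoid K/R (no accidental cleavage sites) so that the
# cassette is the only dibasic-processed region, and avoid C for simplicity
_FLANK_ALPHABET = list("ADEFGHMNPQSTVWY") + list("IL")


def simulate_precursor(peptide_sequence: str, seed: int = 0) -> PrecursorProtein:
    """Emulate a neuropeptide precursor protein around a peptide cassette.

    Layout: initiating Met + random signal region (12-25 residues) + random
    spacer + KR + peptide + G + KR + random C-terminal tail. Only the flanks
    are random; the cassette is deterministic, so cleaving the product and
    amidating its glycine-extended form recovers the input peptide.
    """
    if not peptide_sequence:
        raise InputError("peptide sequence must be non-empty")
    rng = np.random.default_rng(seed)

    def draw(n: int) -> str:
        return "".join(rng.choice(_FLANK_ALPHABET, size=n))

    signal = draw(int(rng.integers(12, 26)))
    spacer = draw(int(rng.integers(3, 9)))
    tail = draw(int(rng.integers(3, 11)))
    seq = "M" + signal + spacer + "KR" + peptide_sequence + "G" + "KR" + tail
    return PrecursorProtein(
        id=f"sim-precursor-{seed}",
        sequence=seq,
        signal_end=1 + len(signal),
    )
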