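"""Peptide-to-spectrum annotation and chemical-modification inference.

Covers the verification side of single-cell peptide identification: matching
the complete theoretical ion set of a candidate peptide to an MS/MS spectrum,
comparing native and synthetic-peptide spectra, flagging phosphocholine and
choline contaminant peaks and the C-terminal-proline side-chain neutral loss,
and reading paired before/after MS1 experiments (on-target acetylation, dye-
induced oxidation) for the functional groups they reveal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from pyteomics import mass as _pmass

from .masscalc import (
    PROLYL_SIDE_CHAIN,
    InputError,
    IonType,
    Peptide,
    TheoreticalIon,
    fragment_ions,
    peptide_mh,
)
from .spectra import MatchTolerance, Peak, Spectrum, filter_significant, match_peaks

__all__ = [
    "PC_MZ",
    "CHOLINE_MZ",
    "IonMatch",
    "AnnotationReport",
    "ModificationInference",
    "annotate_spectrum",
    "compare_spectra",
    "infer_amine_count",
    "infer_oxidizable",
    "report_to_tsv",
]

_PROTON = 1.007276
_ELECTRON = 0.000549

#: Phosphocholine [M+H]+ (C5H14NO4P + proton), the phospholipid head-group
#: contaminant seen in native single-neuron MS/MS spectra.
PC_MZ = _pmass.calculate_mass(formula="C5H14NO4P") + _PROTON
#: Choline cation (C5H14NO+), the PC fragment at m/z 104.1.
CHOLINE_MZ = _pmass.calculate_mass(formula="C5H14NO") - _ELECTRON

_ACETYL = 42.01057
_OX = 15.99491
_DIOX = 31.98983

_ANNOTATION_ION_TYPES = frozenset(
    {
        IonType.a,
        IonType.b,
        IonType.y,
        IonType.internal_b,
        IonType.immonium,
        IonType.precursor,
        IonType.precursor_loss,
    }
)


@dataclass(frozen=True)
class IonMatch:
    """A theoretical ion matched to an observed peak within tolerance."""

    theoretical: TheoreticalIon
    observed: Peak
    error: float  # observed - theoretical, Da


@dataclass(frozen=True)
class AnnotationReport:
    """The outcome of annotating a spectrum with a candidate peptide.

    ``coverage`` is the fraction of the n-1 backbone cleavage sites evidenced
    by a matched b or y ion; ``explained_intensity`` the fraction of total ion
    current carried by matched peaks. Contaminant flags are only set when the
    corresponding peak is present within tolerance; the prolyl neutral-loss
    flag additionally requires a C-terminal proline.
    """

    peptide: Peptide
    matches: tuple[IonMatch, ...]
    coverage: float
    explained_intensity: float
    contaminant_flags: frozenset[str]
    neutral_loss_flags: frozenset[str]
    unexplained_significant: tuple[Peak, ...]


@dataclass(frozen=True)
class ModificationInference:
    """A qualitative inference from a chemical-modification experiment."""

    kind: str  # 'amine count' or 'oxidizable residue'
    value: object  # int count, residue suggestion string, or 'undetermined'
    evidence: tuple[tuple[float, float, float], ...]  # (before, after, delta)


def annotate_spectrum(
    peptide: Peptide,
    spectrum: Spectrum,
    tol: MatchTolerance = MatchTolerance(),
    ion_types: frozenset = _ANNOTATION_ION_TYPES,
) -> AnnotationReport:
    """Annotate an MS/MS spectrum with a peptide's complete theoretical ion set."""
    if spectrum.ms_level != 2:
        raise InputError("annotation requires an MS/MS spectrum")
    ions = fragment_ions(peptide, ion_types)
    matches: list[IonMatch] = []
    matched_peak_mzs: set[float] = set()
    if spectrum.peaks:
        results = match_peaks(spectrum, [ion.mz for ion in ions], tol)
        for ion, res in zip(ions, results):
            if res.peak is not None:
                matches.append(IonMatch(ion, res.peak, res.error))
                matched_peak_mzs.add(res.peak.mz)

    n = len(peptide)
    sites = set()
    for m in matches:
        if m.theoretical.ion_type is IonType.b:
            sites.add(m.theoretical.span[1])
        elif m.theoretical.ion_type is IonType.y:
            sites.add(m.theoretical.span[0] - 1)
    coverage = len(sites) / (n - 1) if n > 1 else 1.0

    tic = spectrum.total_ion_current
    explained = (
        sum(p.intensity for p in spectrum.peaks if p.mz in matched_peak_mzs) / tic
        if tic > 0
        else 0.0
    )

    contaminants = set()
    if spectrum.peaks:
        for name, cmz in (("phosphocholine", PC_MZ), ("choline", CHOLINE_MZ)):
            if match_peaks(spectrum, [cmz], tol)[0].peak is not None:
                contaminants.add(name)

    neutral_losses = set()
    if peptide.sequence.endswith("P") and spectrum.peaks:
        loss_mz = peptide_mh(peptide) - PROLYL_SIDE_CHAIN
        if match_peaks(spectrum, [loss_mz], tol)[0].peak is not None:
            neutral_losses.add("prolyl side-chain")

    significant = filter_significant(spectrum)
    unexplained = tuple(
        p for p in significant.peaks if p.mz not in matched_peak_mzs
    )
    return AnnotationReport(
        peptide=peptide,
        matches=tuple(matches),
        coverage=min(coverage, 1.0),
        explained_intensity=min(explained, 1.0),
        contaminant_flags=frozenset(contaminants),
        neutral_loss_flags=frozenset(neutral_losses),
        unexplained_significant=unexplained,
    )


def compare_spectra(
    a: Spectrum, b: Spectrum, tol: MatchTolerance = MatchTolerance()
) -> tuple[float, list[Peak], list[Peak]]:
    """Greedy nearest-peak comparison of two spectra.

    Peaks are paired greedily by increasing m/z distance within the tolerance
    window; similarity is the Jaccard index |matched| / |union|. Returns the
    similarity and the unmatched peaks of each spectrum, sorted by decreasing
    intensity. Symmetric in its arguments.
    """
    if a.ms_level != b.ms_level:
        raise InputError("spectra must share an MS level")
    pairs = []
    for i, pa in enumerate(a.peaks):
        for j, pb in enumerate(b.peaks):
            d = abs(pa.mz - pb.mz)
            if d <= tol.window:
                pairs.append((d, pa.mz, pb.mz, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    n_matched = 0
    for _, _, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        n_matched += 1
    union = len(a.peaks) + len(b.peaks) - n_matched
    similarity = n_matched / union if union else 1.0
    only_a = sorted(
        (p for i, p in enumerate(a.peaks) if i not in used_a),
        key=lambda p: -p.intensity,
    )
    only_b = sorted(
        (p for j, p in enumerate(b.peaks) if j not in used_b),
        key=lambda p: -p.intensity,
    )
    return similarity, only_a, only_b


_MAX_AMINES = 4


def infer_amine_count(
    before: Spectrum, after: Spectrum, tol: MatchTolerance = MatchTolerance()
) -> ModificationInference:
    """Count free amines from a paired exhaustive-acetylation MS1 experiment.

    Each significant peak of the untreated spectrum is paired with treated-
    spectrum peaks shifted by k x 42.011 Da (k = 0..4, window scaled by k to
    absorb accumulated error); the amine count is the largest complete shift
    multiple observed among paired peaks. Acetylation derivatizes the
    N-terminal alpha-amine and every Lys side chain, so the count equals
    1 + #Lys for an unblocked peptide.
    """
    if before.ms_level != 1 or after.ms_level != 1:
        raise InputError("amine counting uses MS1 spectra")
    sig = filter_significant(before)
    if not sig.peaks:
        # sparse spectra (a handful of real peaks) defeat the median noise
        # estimate; every peak is then treated as significant
        sig = before
    if not sig.peaks or not after.peaks:
        return ModificationInference("amine count", "undetermined", ())
    evidence: list[tuple[float, float, float]] = []
    best_k: Optional[int] = None
    for peak in sig.peaks:
        k_found: Optional[int] = None
        for k in range(_MAX_AMINES, -1, -1):
            window = MatchTolerance(tol.window * max(k, 1))
            res = match_peaks(after, [peak.mz + k * _ACETYL], window)[0]
            if res.peak is not None:
                k_found = k
                if k > 0:
                    evidence.append((peak.mz, res.peak.mz, res.peak.mz - peak.mz))
                break
        if k_found is not None:
            best_k = k_found if best_k is None else max(best_k, k_found)
    if best_k is None:
        return ModificationInference("amine count", "undetermined", tuple(evidence))
    return ModificationInference("amine count", best_k, tuple(evidence))


def infer_oxidizable(
    base_mh: float, spectrum: Spectrum, tol: MatchTolerance = MatchTolerance()
) -> ModificationInference:
    """Read +16/+32 oxidation satellites for oxidizable-residue evidence.

    Methionine sulfoxide gives +16 only; tryptophan gives both +16 and +32
    adducts. Both satellites present therefore suggest Trp (Met remains
    possible alongside); +16 alone is ambiguous between Met and Trp; neither
    satellite means no oxidizable-residue evidence.
    """
    if spectrum.ms_level != 1:
        raise InputError("oxidation inference uses MS1 spectra")
    if match_peaks(spectrum, [base_mh], tol)[0].peak is None:
        raise InputError(f"base peak {base_mh} absent from spectrum")
    hit16 = match_peaks(spectrum, [base_mh + _OX], tol)[0].peak
    hit32 = match_peaks(spectrum, [base_mh + _DIOX], tol)[0].peak
    evidence = []
    if hit16 is not None:
        evidence.append((base_mh, hit16.mz, hit16.mz - base_mh))
    if hit32 is not None:
        evidence.append((base_mh, hit32.mz, hit32.mz - base_mh))
    if hit16 is not None and hit32 is not None:
        value = "W suggested, M possible"
    elif hit16 is not None:
        value = "M or W possible"
    else:
        value = "none"
    return ModificationInference("oxidizable residue", value, tuple(evidence))


def report_to_tsv(report: AnnotationReport, path) -> None:
    """Export ion matches as TSV (ion_type, span, theoretical, observed, error,
    intensity)."""
    with open(path, "w") as fh:
        fh.write("ion_type\tspan\ttheoretical_mz\tobserved_mz\terror\tintensity\n")
        for m in sorted(report.matches, key=lambda m: m.theoretical.mz):
            t = m.theoretical
            fh.write(
                f"{t.ion_type.value}\t{t.span[0]}-{t.span[1]}\t{t.mz:.6f}\t"
                f"{m.observed.mz:.6f}\t{m.error:+.6f}\t{m.observed.intensity:.3f}\n"
            )
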