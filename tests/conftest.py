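"""Shared fixtures: the worked-example peptide and its synthetic spectra."""

import pytest

from maldipep.masscalc import CTerm, IonType, Peptide, fragment_ions, peptide_mh
from maldipep.spectra import MatchTolerance, Peak, Spectrum

#: The study's worked example: an 11-residue RPamide neuropeptide whose
#: glycine-extended precursor form appears alongside it in single-cell MS1.
NLP22 = "SLASGRWGLRP"
NLP22_GLY = "SLASGRWGLRPG"

AA20 = list("ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture
def nlp22():
    return Peptide(NLP22, CTerm.amide)


@pytest.fixture
def nlp22_gly():
    return Peptide(NLP22_GLY, CTerm.acid)


@pytest.fixture
def tol():
    return MatchTolerance(0.2)


def theoretical_spectrum(peptide, ion_types, intensity=100.0):
    """Noiseless spectrum containing exactly the requested theoretical ions."""
    ions = fragment_ions(peptide, ion_types)
    peaks = tuple(Peak(ion.mz, intensity) for ion in ions)
    return Spectrum(
        peaks, ms_level=2, precursor_mh=peptide_mh(peptide), source="theoretical"
    )


@pytest.fixture
def nlp22_full_spectrum(nlp22):
    """Complete a/b/y/internal/immonium spectrum of the worked example."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # isobaric theoretical ions merge
        return theoretical_spectrum(
            nlp22,
            {IonType.a, IonType.b, IonType.y, IonType.internal_b, IonType.immonium},
        )


@pytest.fixture
def nlp22_by_spectrum(nlp22):
    return theoretical_spectrum(nlp22, {IonType.b, IonType.y})


def random_peptide(rng, min_len=8, max_len=15, c_term=None):
    """A uniform random peptide over the 20 standard residues."""
    n = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(AA20, size=n))
    if c_term is None:
        c_term = CTerm.amide if rng.random() < 0.5 else CTerm.acid
    return Peptide(seq, c_term)
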