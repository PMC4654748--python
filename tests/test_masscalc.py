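"""Monoisotopic mass bookkeeping: worked examples, ion identities, oracle."""

import numpy as np
import pytest

from maldipep import masscalc as mc
from maldipep.masscalc import (
    HYDROGEN,
    AlphabetError,
    CTerm,
    InputError,
    IonType,
    Peptide,
    classify_mass_shift,
    fragment_ions,
    peptide_mh,
)

from conftest import random_peptide

# independent atom-composition oracle: residue formulas x atomic masses
_ATOM = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048, "O": 15.9949146196, "S": 31.97207100}
_FORMULA = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO", "V": "C5H9NO",
    "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO", "I": "C6H11NO", "N": "C4H6N2O2",
    "D": "C4H5NO3", "Q": "C5H8N2O2", "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS",
    "H": "C6H7N3O", "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}


def _formula_mass(formula: str) -> float:
    import re

    total = 0.0
    for element, count in re.findall(r"([A-Z])(\d*)", formula):
        total += _ATOM[element] * (int(count) if count else 1)
    return total


def oracle_mh(sequence: str, c_term: CTerm) -> float:
    """MH+ summed from elemental compositions (independent of the residue table)."""
    residues = sum(_formula_mass(_FORMULA[aa]) for aa in sequence)
    if c_term is CTerm.amide:
        terminal = _ATOM["N"] + 4 * _ATOM["H"]
    else:
        terminal = _ATOM["O"] + 3 * _ATOM["H"]
    return residues + terminal


class TestPeptideMH:
    @pytest.mark.parametrize(
        "sequence,c_term,printed",
        [
            ("SLASGRWGLRP", CTerm.amide, 1198.7),  # the VI/DI neuron peak
            ("SLASGRWGLRPG", CTerm.acid, 1256.7),  # glycine-extended intermediate
            ("G", CTerm.acid, 76.0),
        ],
    )
    def test_printed_values(self, sequence, c_term, printed):
        assert round(peptide_mh(Peptide(sequence, c_term)), 1) == printed

    def test_glycine_residue_plus_acid_terminus(self):
        assert peptide_mh(Peptide("G", CTerm.acid)) == pytest.approx(
            57.02146 + 19.01839, abs=1e-9
        )

    def test_amide_acid_offset(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = random_peptide(rng, c_term=CTerm.amide)
            acid = Peptide(p.sequence, CTerm.acid)
            assert peptide_mh(p) == pytest.approx(peptide_mh(acid) - 0.98402, abs=1e-9)

    def test_glycine_extension_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = random_peptide(rng, c_term=CTerm.amide)
            ext = Peptide(p.sequence + "G", CTerm.acid)
            assert peptide_mh(ext) - peptide_mh(p) == pytest.approx(58.00548, abs=1e-9)

    def test_oracle_equivalence(self):
        """Agreement with an independent atom-composition sum, 100 random peptides."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = random_peptide(rng, min_len=5, max_len=20)
            assert peptide_mh(p) == pytest.approx(
                oracle_mh(p.sequence, p.c_term), abs=1e-4
            )

    def test_modifications_shift_mass(self):
        base = Peptide("SLASGRWGLRP", CTerm.amide)
        acetyl = mc.get_modification("acetyl")
        modified = Peptide("SLASGRWGLRP", CTerm.amide, ((acetyl, "N-term"),))
        assert peptide_mh(modified) - peptide_mh(base) == pytest.approx(42.01057)

    def test_errors(self):
        with pytest.raises(AlphabetError):
            Peptide("SLAZ", CTerm.amide)
        with pytest.raises(InputError):
            Peptide("", CTerm.amide)
        with pytest.raises(InputError):
            Peptide("AG", CTerm.amide, ((mc.get_modification("acetyl"), 5),))


class TestFragmentIons:
    def test_b2_y1_worked_example(self, nlp22):
        ions = {('b', 2): None, ('y', 1): None}
        for ion in fragment_ions(nlp22, {IonType.b, IonType.y}):
            if ion.ion_type is IonType.b and ion.span == (1, 2):
                assert ion.mz == pytest.approx(201.124, abs=1e-3)
            if ion.ion_type is IonType.y and ion.span == (11, 11):
                assert ion.mz == pytest.approx(115.087, abs=1e-3)

    def test_complementarity_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = random_peptide(rng)
            mh = peptide_mh(p)
            ions = fragment_ions(p, {IonType.b, IonType.y})
            b = {i.span[1]: i.mz for i in ions if i.ion_type is IonType.b}
            y = {len(p) - i.span[0] + 1: i.mz for i in ions if i.ion_type is IonType.y}
            for k in range(1, len(p)):
                assert b[k] + y[len(p) - k] - mh == pytest.approx(HYDROGEN, abs=1e-6)

    def test_index_ranges_and_internal_spans(self, nlp22):
        n = len(nlp22)
        ions = fragment_ions(nlp22, {IonType.b, IonType.y, IonType.internal_b})
        b_spans = [i.span for i in ions if i.ion_type is IonType.b]
        assert b_spans == [(1, k) for k in range(1, n)]
        for i in ions:
            if i.ion_type is IonType.internal_b:
                lo, hi = i.span
                assert 2 <= lo < hi <= n - 1

    def test_a_and_immonium_offsets(self, nlp22):
        ions = fragment_ions(nlp22, {IonType.a, IonType.b, IonType.immonium})
        a = {i.span: i.mz for i in ions if i.ion_type is IonType.a}
        b = {i.span: i.mz for i in ions if i.ion_type is IonType.b}
        for span in a:
            assert b[span] - a[span] == pytest.approx(27.99491, abs=1e-9)
        imm = [i for i in ions if i.ion_type is IonType.immonium]
        trp = next(i for i in imm if nlp22.sequence[i.span[0] - 1] == "W")
        assert trp.mz == pytest.approx(186.07931 - 26.98709, abs=1e-6)

    def test_cterm_proline_neutral_loss(self, nlp22):
        ions = fragment_ions(nlp22, {IonType.precursor_loss})
        assert len(ions) == 1
        assert ions[0].mz == pytest.approx(peptide_mh(nlp22) - 42.04695, abs=1e-6)
        no_pro = Peptide("SLASGRWGLRA", CTerm.amide)
        assert fragment_ions(no_pro, {IonType.precursor_loss}) == []

    def test_single_residue_has_no_sequence_ions(self):
        assert fragment_ions(Peptide("G", CTerm.acid), {IonType.b, IonType.y}) == []

    def test_unknown_type_rejected(self, nlp22):
        with pytest.raises((InputError, ValueError)):
            fragment_ions(nlp22, {"z"})
        with pytest.raises(InputError):
            mc.fragment_ions_from_masses([57.0], CTerm.acid, set())


class TestClassifyMassShift:
    def test_58_is_glycine_extension(self):
        names = [m.name for m in classify_mass_shift(58.0, 0.2)]
        assert names == ["glycine-extension"]

    def test_42_is_ambiguous(self):
        names = {m.name for m in classify_mass_shift(42.0, 0.2)}
        assert names == {"acetyl", "prolyl side-chain loss"}

    def test_zero_shift_unexplained(self):
        assert classify_mass_shift(0.0, 0.2) == []

    def test_multiples_of_acetyl_and_oxidation(self):
        assert any(
            m.modification.name == "acetyl" and m.count == 2
            for m in classify_mass_shift(84.02, 0.2)
        )
        assert any(
            m.modification.name == "oxidation" and m.count == 2
            for m in classify_mass_shift(-31.99, 0.2)
        )

    def test_ordering_by_error(self):
        matches = classify_mass_shift(42.011, 0.2)
        errors = [abs(m.error) for m in matches]
        assert errors == sorted(errors)

    def test_bad_tolerance(self):
        with pytest.raises(InputError):
            classify_mass_shift(58.0, 0.0)


def test_registry_contents_and_export(tmp_path):
    expected = {
        "acetyl": 42.01057,
        "oxidation": 15.99491,
        "dioxidation": 31.98983,
        "glycine-extension": 58.00548,
        "prolyl side-chain loss": -42.04695,
    }
    registry = {m.name: m.delta for m in mc.MODIFICATION_REGISTRY}
    assert registry == pytest.approx(expected)
    out = tmp_path / "mods.tsv"
    mc.write_modification_registry(out)
    lines = out.read_text().splitlines()
    assert lines[0] == "name\tdelta\tsite_class"
    assert len(lines) == 1 + len(expected)


def test_free_amine_count():
    assert mc.free_amine_count(Peptide("SLASGRWGLRP", CTerm.amide)) == 1
    assert mc.free_amine_count(Peptide("SAKGKWGLR", CTerm.acid)) == 3
    blocked = Peptide("SLAS", CTerm.amide, ((mc.get_modification("acetyl"), "N-term"),))
    assert mc.free_amine_count(blocked) == 0


def test_ion_export_tsv(tmp_path, nlp22):
    ions = fragment_ions(nlp22, {IonType.b, IonType.y})
    out = tmp_path / "ions.tsv"
    mc.ions_to_tsv(ions, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "ion_type\tspan\tmz"
    assert len(lines) == 1 + len(ions)


# property-based check of the terminal-group identities over arbitrary sequences
from hypothesis import given, settings, strategies as st

_sequences = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=25)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(_sequences)
def test_terminal_identities_hold_for_arbitrary_sequences(sequence):
    """Amide/acid offset and glycine-extension identity for any sequence."""
    amide = peptide_mh(Peptide(sequence, CTerm.amide))
    acid = peptide_mh(Peptide(sequence, CTerm.acid))
    extended = peptide_mh(Peptide(sequence + "G", CTerm.acid))
    assert amide == pytest.approx(acid - 0.98402, abs=1e-9)
    assert extended - amide == pytest.approx(58.00548, abs=1e-9)
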