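# maldipep

Single-cell MALDI-TOF/TOF neuropeptide identification: from centroided peak
lists to sequenced, post-translationally processed peptides.

Individually dissected invertebrate neurons yield MS1 spectra with a handful
of peptide peaks and MS/MS spectra of singly protonated precursors. Working
from such data, a peptide is identified by (1) reading the b/y fragment-ion
ladders de novo, (2) verifying the candidate against its complete theoretical
ion set (a/b/y ions, internal fragments, immonium ions), (3) interpreting
satellite MS1 peaks as chemical evidence — a +58 Da partner is the
glycine-extended amidation intermediate, +16/+32 Da partners indicate
oxidizable Met/Trp, an exhaustive-acetylation +42·k Da shift counts free
amines — and (4) reconciling the peptide with its precursor protein, whose
cassette is flanked by dibasic convertase sites and ends in the glycine that
becomes the C-terminal amide. `maldipep` implements this whole workflow as a
library plus a small CLI, together with seeded generators that emulate the
instrument's output (ion detection dropout, m/z jitter, chemical noise,
phosphocholine/choline contamination, calibration drift) so every stage is
testable without instrument data.

## The core calculation

For a peptide with residue masses $r_1..r_n$, singly protonated monoisotopic
ions follow the hydrogen-atom convention of the classic peptide calculators:

$$\mathrm{MH^+} = \sum_i r_i + T, \qquad T_{\text{amide}} = 18.03437,\ T_{\text{acid}} = 19.01839$$

$$b_k = \sum_{i\le k} r_i + 1.00782,\qquad y_k = \sum_{i>n-k} r_i + T,\qquad a_k = b_k - 27.99491$$

so that $b_k + y_{n-k} = \mathrm{MH^+} + 1.00782$. De novo sequencing seeds
candidate $b_2$ and $y_1$ ions, grows each series by reading peak-to-peak
mass differences as residues (bridging single missing ions as unordered
residue pairs), and ranks completed candidates by the fraction of total ion
current their theoretical ion set explains, penalized by the mean mass error
of their backbone ladder. Residues indistinguishable at the working ±0.2 Da
tolerance are reported as ambiguity classes: Ile/Leu as `J`, Lys/Gln as
`[K/Q]`.

## Worked example

```python
from maldipep import (CTerm, Peptide, peptide_mh, SimConfig,
                      simulate_msms, denovo_sequence, MatchTolerance)

pep = Peptide("SLASGRWGLRP", CTerm.amide)
print(round(peptide_mh(pep), 1))                  # 1198.7
print(round(peptide_mh(Peptide("SLASGRWGLRPG", CTerm.acid)), 1))  # 1256.7

spectrum = simulate_msms(pep, SimConfig(seed=5))  # realistic MS/MS
top = denovo_sequence(spectrum, MatchTolerance(0.2))[0]
print(top.canonical, top.c_term.value, round(top.score, 3))
# SJASGRWGJRP amide 0.916
```

The two MH⁺ values are the mature amidated peptide and its glycine-extended
intermediate — 58 Da apart (the Gly residue, 57.02, plus the amide→acid
difference, 0.98). The de novo result recovers the sequence up to the
inherent Ile/Leu ambiguity (`J`), with 91.6% of the simulated spectrum's ion
current explained by the candidate's ion set.

The same workflow from the shell:

```
maldipep simulate --peptide SLASGRWGLRP --cterm amide --seed 5 --out msms.mgf
maldipep denovo --msms msms.mgf --tol 0.2 --top 3
maldipep annotate --peptide SLASGRWGLRP --cterm amide --msms msms.mgf
maldipep modcheck --delta 58.0
```

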