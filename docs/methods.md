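# Methods

This note documents the models, conventions, and design choices behind
`maldipep`: what each stage assumes, which knobs matter, and what the
synthetic-data generators do and do not emulate.

## Mass conventions

All arithmetic is monoisotopic and singly protonated; MALDI of small peptides
produces essentially only 1+ ions, and the printed one-decimal m/z values of
TOF/TOF work match monoisotopic masses. Ion formulas follow the hydrogen-atom
convention of the classic peptide fragmentation calculators: the charge
carrier is taken as 1.00782 Da (an H atom) rather than the bare proton
(1.00728 Da). The 0.55 mDa difference is far below the ±0.2 Da working
tolerance and the convention makes the b/y complementarity identity
`b_k + y_(n−k) = MH+ + 1.00782` exact. Terminal constants: amide 18.03437 Da
(N + 4H), free acid 19.01839 Da (O + 3H). The two contaminant references —
phosphocholine [M+H]+ 184.073 and the choline cation 104.107 — are computed
from elemental composition with the true proton/electron masses, because
they are pinned at three decimals.

The modification registry is deliberately tiny and closed: acetylation
(+42.01057, free amines), oxidation (+15.99491, Met/Trp), dioxidation
(+31.98983, Trp), glycine extension (+58.00548 = Gly 57.02146 + amide→acid
0.98402), and the C-terminal-proline side-chain neutral loss (−42.04695,
C3H6). These are the shifts this workflow actually interprets; the registry
is serializable as plain text for users who need more.

At ±0.2 Da, acetylation (+42.011) and the prolyl side-chain loss (−42.047)
are indistinguishable by magnitude, so `classify_mass_shift` reports both
and the annotation layer applies context: the neutral-loss flag requires a
C-terminal proline, while an acetylation reading requires a paired
before/after derivatization experiment.

## Significance filtering and recalibration

Baseline noise is estimated as the median peak intensity of the centroided
list — robust when a spectrum is a few intense peptide peaks on a sea of
low-level chemical noise — and a peak is significant at ≥ 2× that estimate
(the noise factor is a parameter; the noise value used is recorded in the
spectrum's metadata so the filter is reproducible). The estimate degrades
when real peaks are the majority of the list: the amine-counting routine
therefore falls back to treating all peaks as significant when the filter
empties a sparse spectrum.

External recalibration matches user-supplied reference masses (the known
peptide peaks of a reference cell type; they are configuration, not baked
in) to observed peaks within the tolerance window and fits
`corrected = slope·observed + offset` by least squares (a single anchor
fixes only the offset). Zero matched anchors is reported as a failure with
the spectrum returned untouched. Matching uses an absolute, symmetric ±Da
window (default 0.2 Da) rather than ppm, which is how TOF/TOF assignments
at this mass range are actually made; distance ties break toward the more
intense, then the lower-m/z peak.

## De novo sequencing

The sequencer reproduces manual TOF/TOF interpretation as a bounded,
deterministic beam search on the cumulative residue-mass axis:

1. **Seeding.** Candidate b2 ions are peaks whose m/z − 1.00782 matches a
   residue-pair sum within tolerance (the pair is unordered until other
   evidence resolves it); candidate y1 ions match residue + terminal
   constant, under both amide and acid hypotheses. Zero-mass roots always
   run alongside the seeds with a reduced beam, so a direction survives the
   loss of its seeding ion.
2. **Extension.** From each series tip, the mass difference to a further
   peak is read as a single residue when one fits; otherwise as an unordered
   dipeptide bridging one missing ion (at most 3 bridges per series; longer
   gaps end the series). A difference a single residue explains is never
   also read as a dipeptide: Asn and Gly-Gly are exactly isobaric, and
   offering both readings everywhere would double the search for
   interpretations no mass measurement can separate.
3. **Search discipline.** The search works with exact residue masses
   (Ile/Leu share one mass and the label `J`; near-isobars such as Lys/Gln
   stay distinct internally and merge only in the reported sequence). Each
   live series accumulates supporting evidence — anchor-peak intensity plus
   the intensity of complementary partners at `MH+ + 1.00782 − m/z`, the
   b/y complementarity filter applied during search — and the frontier keeps
   the best 300 series, at most 3 per distinct cumulative mass. The per-tip
   cap matters: a noise peak that happens to split one residue step creates
   a detour that rejoins the true ladder, and unchecked detours multiply
   into families that crowd out everything else.
4. **Completion and expansion.** A series completes when the remaining mass
   to the precursor target is zero, one residue, or one unordered pair.
   Completed series expand their unordered pairs into explicit orders
   (capped at 32), are deduplicated, and must account for the precursor mass
   within tolerance.
5. **Scoring and ranking.** Every surviving candidate is scored against its
   full theoretical ion set (a, b, y, internal-b, immonium) with vectorized
   window matching; when more than 500 candidates survive, a vectorized
   backbone prescore (b/y ladder completeness and mass accuracy) selects the
   500 to score fully. Ranking: explained fraction of total ion current
   penalized by mean backbone mass error at 10 TIC-fraction units per Da
   (i.e. 0.01 Da of systematic ladder offset cancels a 10%-of-TIC
   advantage), binned at 1%; ties break by backbone matched fraction,
   backbone error, full-set matched fraction, full-set error, and finally
   canonical label. The penalty and the bin express two facts about this
   data: a systematic ladder offset is strong evidence against a reading on
   a calibrated instrument, and a sub-percent intensity edge is usually one
   coincidental noise peak. A raw matched-ion count is deliberately not
   used: longer wrong readings carry larger theoretical sets and match more
   ions by chance.

Measured behaviour under the test conditions (seeded): 200/200 top-1
recovery on noiseless complete b/y spectra of random 8–15-mers; 176/200
(88%) with per-ion detection 0.9 and 20 uniform noise peaks; 85/100 seeds
recover the worked example from fully realistic simulations (jitter, all
ion types, intensity noise).

Some readings are physically unresolvable and are treated as correct in the
recovery tests: besides the Ile/Leu and (at 0.2 Da) Lys/Gln classes, a
C-terminal Asn free acid has the same elemental composition as a C-terminal
Asp amide (and Gln-acid ≡ Glu-amide), so every fragment mass of the two
readings coincides at any tolerance.

## Annotation and modification inference

Annotation matches the complete theoretical ion set (including precursor and,
for C-terminal-Pro peptides, the −42.047 neutral loss) against the spectrum,
reports backbone cleavage-site coverage and explained intensity, lists
significant unexplained peaks, and flags phosphocholine/choline peaks —
diagnostic of a real cell on the target, since synthetic-peptide spectra
lack them. Spectrum comparison is a greedy nearest-pair matching with a
Jaccard similarity; it is symmetric and intensity-agnostic, since MALDI
intensities are not quantitative.

Amine counting pairs each significant untreated-spectrum peak with treated-
spectrum peaks at +k·42.011 (k ≤ 4, window scaled by k), taking the largest
complete-shift multiple observed; exhaustive acetylation derivatizes the
N-terminal alpha-amine plus every Lys. Oxidation inference is a qualitative
rule table — +16 and +32 together suggest Trp (Met possible), +16 alone is
Met-or-Trp — matching the qualitative nature of the dye-induced oxidation
evidence itself.

## Precursor processing

Cleavage cuts after every dibasic pair (KR/RR/KK/RK) downstream of the
annotated signal region, optionally after isolated K/R not followed by Pro
(a standard convertase constraint); C-terminal basic residues are then
trimmed (carboxypeptidase), and a product ending in Gly is emitted both as
the glycine-extended free acid and as the amidated mature peptide — the pair
differs by exactly 58.005 Da, which is how processing intermediates are
recognized in MS1. KK-derived products carry a "possibly incomplete" flag
(KK sites are often partially processed in vivo). The signal boundary is an
annotation input from an external predictor, never computed here.

Homolog discovery uses full Smith–Waterman local alignment under PAM30 with
affine gaps (open 9, extend 1: a gap of length L costs 9 + L), implemented
on Biopython's `PairwiseAligner`; word-size seeding and E-value statistics
are out of scope, and full dynamic programming can only find equal-or-better
alignments than a seeded heuristic. The nematode RPamide-family motif
`S[AML]A[INS]GR[AMW][GQ][MFL]RPG` ships as a ready-made pattern; group
classification reads the amidated C-terminal tripeptide (-FRP = group 1,
-LRP = group 2).

## Synthetic data

The generators emulate exactly the features the pipeline consumes, as pure
functions of (inputs, seed):

- **MS/MS**: each theoretical ion drawn with a per-type detection
  probability (defaults y 0.95, b 0.90, a 0.6, internal 0.5, immonium 0.6 —
  spectra carry "nearly the full" b/y set while satellites are less
  reliable), Gaussian m/z jitter (sd 0.02 Da), lognormal multiplicative
  intensity noise (sd 0.5) around per-type base levels ordered
  y > b > a > immonium > internal, a fixed count of uniform noise peaks
  (default 20; fixed, not Poisson, for determinism at a given seed),
  optional phosphocholine/choline peaks, and a final affine calibration
  distortion (the declared precursor is recorded pre-distortion so
  recalibration can be tested as parameter recovery).
- **MS1**: one MH+ peak per peptide within the 500–4000 Da acquisition
  window, plus satellites at +58.005 (glycine-extended, relative intensity
  0.3), +15.995 (0.05) and +31.990 (0.02).
- **Precursors**: Met + random signal region (12–25 residues) + spacer +
  `KR` + peptide + `G` + `KR` + tail; only the flanks are random, and they
  avoid K/R so the cassette is the only dibasic-processed region.

What the generators do **not** model: isotope envelopes, multiply charged
ions, matrix clusters, detector saturation, ion suppression, and realistic
peak-count/dynamic-range statistics of real single cells (not tabulated
anywhere usable). Passing tests therefore demonstrate the correctness and
robustness of the interpretation logic under controlled imperfections, not
instrument-grade performance on real spectra.

A note on the precursor round-trip tests: peptides containing an internal
dibasic pair are excluded from the round-trip property, because the
convertase model cleaves them by construction — mature secreted peptides do
not retain internal dibasic sites.

## Degenerate inputs and numerical choices

Duplicate centroids within 1 µDa merge by intensity summation (with a
warning); a single-residue peptide has no sequence ions (not an error);
uniform-intensity spectra filter to empty at noise factor 2 (documented
consequence of the median rule); de novo on a precursor mass no residue
composition can reach returns an empty list and logs the longest partial
series. All floating-point comparisons in the library use explicit absolute
windows; nothing is rounded internally — rounding happens only when values
are compared with printed one-decimal readings or written to text formats
(6-decimal m/z).

## Problem sizes

The bundled test suite uses 200-peptide recovery suites (lengths 8–15), 100
seeds for the end-to-end identification rate, 1000 peptides for the
complementarity invariant, 50 spectra for calibration recovery, and 200
random pairs (lengths ≤ 8) against the exhaustive alignment oracle — sizes
chosen so the whole suite runs in a few minutes on one core while holding
the statistical guarantees stated above.
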