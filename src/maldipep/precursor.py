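"""Prohormone processing prediction and neuropeptide homolog discovery.

Neuropeptide precursors are processed by prohormone convertases at basic-
residue cleavage sites, trimmed by carboxypeptidase, and C-terminally amidated
when the trimmed product ends in glycine. This module predicts those products
from an annotated precursor sequence, computes their MH+ masses, scans for the
conserved nematode RPamide (nlp-22 family) motif, classifies peptides into the
-FRPamide / -LRPamide clade groups, and performs PAM30 local alignment for
short-query homolog searches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from . import masscalc
from .masscalc import CTerm, InputError, Peptide

__all__ = [
    "PrecursorProtein",
    "CleavageProduct",
    "MotifPattern",
    "NLP22_MOTIF",
    "AlignmentResult",
    "read_fasta",
    "cleave",
    "predict_masses",
    "motif_scan",
    "classify_group",
    "local_align",
    "products_to_tsv",
]

_BASIC = {"K", "R"}
_DIBASIC = {"KR", "RR", "KK", "RK"}


@dataclass(frozen=True)
class PrecursorProtein:
    """An annotated precursor: sequence plus the signal-region boundary.

    ``signal_end`` is the 1-based, inclusive index of the last signal-peptide
    residue; the signal region is an annotation input (from an external
    predictor), never computed here.
    """

    id: str
    sequence: str
    signal_end: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError("precursor sequence must be non-empty")
        if self.signal_end is not None and not (
            1 <= self.signal_end < len(self.sequence)
        ):
            raise InputError(
                f"signal_end {self.signal_end} outside 1..{len(self.sequence) - 1}"
            )


@dataclass(frozen=True)
class CleavageProduct:
    """One predicted peptide product of precursor processing.

    ``span`` covers the raw (post-trimming) sequence in 1-based inclusive
    precursor coordinates; ``mature`` is the final peptide (glycine removed
    when amidated). ``flags`` may include ``KK-site`` (KK cleavage is often
    incomplete in vivo), ``monobasic-site``, and ``unprocessed N-terminus``
    (no signal annotation and product starts at residue 1).
    """

    span: tuple[int, int]
    raw: str
    mature: str
    c_term: CTerm
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.mature:
            raise InputError("mature product sequence must be non-empty")
        if self.c_term is CTerm.amide and not self.raw.endswith("G"):
            raise InputError("amidated products must derive from a C-terminal G")


def read_fasta(path) -> list[PrecursorProtein]:
    """Read precursor sequences from FASTA (signal_end not encoded in FASTA;
    set it afterwards where known)."""
    return [
        PrecursorProtein(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def cleave(
    precursor: PrecursorProtein, use_monobasic: bool = False
) -> list[CleavageProduct]:
    """Predict convertase cleavage products of a precursor.

    Cuts after every dibasic pair (KR/RR/KK/RK) and, when ``use_monobasic``,
    after isolated K/R not followed by proline. C-terminal basic residues are
    trimmed from each segment (the carboxypeptidase step); products then
    ending in G are emitted twice: as the glycine-extended free acid and as
    the amidated mature form. The signal region is excluded from products.
    """
    seq = precursor.sequence
    start0 = precursor.signal_end if precursor.signal_end is not None else 0
    region = seq[start0:]
    # cut positions are indices (0-based, relative to region) AFTER which to cut
    cuts: list[tuple[int, frozenset[str]]] = []
    i = 0
    while i < len(region) - 1:
        pair = region[i : i + 2]
        if pair in _DIBASIC:
            flags = frozenset({"KK-site"}) if pair == "KK" else frozenset()
            cuts.append((i + 2, flags))
            i += 2
            continue
        i += 1
    if use_monobasic:
        pair_members = set()
        for cut_pos, _ in cuts:
            pair_members.update((cut_pos - 2, cut_pos - 1))
        for j, aa in enumerate(region):
            if aa not in _BASIC or j in pair_members:
                continue
            if (j > 0 and region[j - 1] in _BASIC) or (
                j + 1 < len(region) and region[j + 1] in _BASIC
            ):
                continue  # not an isolated basic residue
            if j + 1 < len(region) and region[j + 1] == "P":
                continue  # convertases do not cleave before proline
            cuts.append((j + 1, frozenset({"monobasic-site"})))
        cuts.sort(key=lambda t: t[0])

    products: list[CleavageProduct] = []
    seg_start = 0
    boundaries = cuts + [(len(region), frozenset())]
    for cut_pos, site_flags in boundaries:
        segment = region[seg_start:cut_pos]
        seg_origin = seg_start
        seg_start = cut_pos
        if not segment:
            continue
        trimmed = segment.rstrip("KR")
        if not trimmed:
            continue
        span = (start0 + seg_origin + 1, start0 + seg_origin + len(trimmed))
        flags = set(site_flags)
        if precursor.signal_end is None and span[0] == 1:
            flags.add("unprocessed N-terminus")
        if trimmed.endswith("G"):
            products.append(
                CleavageProduct(span, trimmed, trimmed, CTerm.acid, frozenset(flags))
            )
            if len(trimmed) > 1:
                products.append(
                    CleavageProduct(
                        span, trimmed, trimmed[:-1], CTerm.amide, frozenset(flags)
                    )
                )
        else:
            products.append(
                CleavageProduct(span, trimmed, trimmed, CTerm.acid, frozenset(flags))
            )
    return products


def predict_masses(
    products: Sequence[CleavageProduct],
) -> list[tuple[CleavageProduct, float]]:
    """Attach the singly protonated monoisotopic MH+ to each product."""
    return [
        (p, masscalc.peptide_mh(Peptide(p.mature, p.c_term))) for p in products
    ]


@dataclass(frozen=True)
class MotifPattern:
    """An ungapped motif: one allowed-residue set per position.

    Accepts bracket notation, e.g. the conserved nematode RPamide-precursor
    motif ``S[AML]A[INS]GR[AMW][GQ][MFL]RPG``.
    """

    positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise InputError("motif must have at least one position")

    @classmethod
    def from_string(cls, pattern: str) -> "MotifPattern":
        positions: list[frozenset[str]] = []
        i = 0
        while i < len(pattern):
            ch = pattern[i]
            if ch == "[":
                j = pattern.index("]", i)
                positions.append(frozenset(pattern[i + 1 : j]))
                i = j + 1
            else:
                positions.append(frozenset(ch))
                i += 1
        return cls(tuple(positions))

    def __len__(self) -> int:
        return len(self.positions)


#: The conserved precursor motif of the nematode nlp-22 peptide family
#: (the mature peptide plus its amidation glycine).
NLP22_MOTIF = MotifPattern.from_string("S[AML]A[INS]GR[AMW][GQ][MFL]RPG")


def motif_scan(sequence: str, pattern: MotifPattern) -> list[tuple[int, int]]:
    """All ungapped motif matches, as 1-based inclusive spans."""
    n, m = len(sequence), len(pattern)
    spans = []
    for start in range(n - m + 1):
        if all(sequence[start + k] in pattern.positions[k] for k in range(m)):
            spans.append((start + 1, start + m))
    return spans


def classify_group(sequence: str, c_term: CTerm) -> str:
    """Clade-group classification of an amidated RPamide peptide.

    Group 1 peptides (clades IVa/V) end -FRPamide; group 2 (clades III/IVb)
    end -LRPamide; anything else is 'other'. The classification is defined on
    amidated peptides only.
    """
    if CTerm(c_term) is not CTerm.amide:
        warnings.warn("group classification is defined on amidated peptides", stacklevel=2)
        return "other"
    if sequence.endswith("FRP"):
        return "group1"
    if sequence.endswith("LRP"):
        return "group2"
    return "other"


@dataclass(frozen=True)
class AlignmentResult:
    """A local alignment under PAM30 with affine gaps.

    ``score`` is in PAM30 units; a gap of length L costs
    ``gap_open + L * gap_extend``. The aligned strings use '-' for gaps.
    """

    score: float
    query_span: tuple[int, int]  # 1-based inclusive
    target_span: tuple[int, int]
    aligned_query: str
    aligned_target: str


_PAM30 = substitution_matrices.load("PAM30")


def local_align(
    query: str,
    target: str,
    gap_open: float = 9.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment with PAM30 scoring.

    Full dynamic programming (no word-size seeding or E-value statistics), as
    appropriate for short neuropeptide queries. Deterministic: of co-optimal
    alignments the aligner's first enumeration order is returned.
    """
    if not query or not target:
        raise InputError("query and target must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _PAM30
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    alignments = aligner.align(query, target)
    if len(alignments) == 0 or alignments.score <= 0:
        # no residue pair scores positively: the optimal local alignment is empty
        return AlignmentResult(0.0, (0, 0), (0, 0), "", "")
    aln = alignments[0]
    (qstart, qend) = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    (tstart, tend) = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
    aligned_q, aligned_t = _aligned_strings(aln)
    return AlignmentResult(
        score=float(aln.score),
        query_span=(qstart + 1, qend),
        target_span=(tstart + 1, tend),
        aligned_query=aligned_q,
        aligned_target=aligned_t,
    )


def _aligned_strings(aln) -> tuple[str, str]:
    q_blocks, t_blocks = aln.aligned
    q, t = aln.sequences
    out_q, out_t = [], []
    prev_q_end, prev_t_end = q_blocks[0][0], t_blocks[0][0]
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        if qs > prev_q_end:  # gap in target
            out_q.append(q[prev_q_end:qs])
            out_t.append("-" * (qs - prev_q_end))
        if ts > prev_t_end:  # gap in query
            out_q.append("-" * (ts - prev_t_end))
            out_t.append(t[prev_t_end:ts])
        out_q.append(q[qs:qe])
        out_t.append(t[ts:te])
        prev_q_end, prev_t_end = qe, te
    return "".join(out_q), "".join(out_t)


def products_to_tsv(
    precursor: PrecursorProtein,
    products_with_masses: Sequence[tuple[CleavageProduct, float]],
    path,
) -> None:
    """Emit products and masses as TSV (id, span, raw, mature, c_term, MH+, flags)."""
    with open(path, "w") as fh:
        fh.write("id\tspan\traw\tmature\tc_term\tmh\tflags\n")
        for product, mh in products_with_masses:
            fh.write(
                f"{precursor.id}\t{product.span[0]}-{product.span[1]}\t{product.raw}\t"
                f"{product.mature}\t{product.c_term.value}\t{mh:.5f}\t"
                f"{','.join(sorted(product.flags))}\n"
            )
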