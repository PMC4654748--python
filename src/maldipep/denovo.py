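"""De novo peptide sequencing from singly protonated MS/MS peak lists.

The reconstruction mirrors manual TOF/TOF interpretation: candidate b2 and y1
ions seed N-terminal (b) and C-terminal (y) ion series; each series grows by
reading the mass difference to the next compatible peak as an amino-acid
residue, bridging a single missing ion as an unordered dipeptide gap; a series
completes when its cumulative residue mass accounts for the declared precursor
MH+. Completed series become full-length sequence candidates, which are then
re-scored against the complete theoretical ion set (a/b/y, internal fragments,
immonium ions) and ranked by the fraction of total ion current they explain,
with backbone-series completeness and mass accuracy breaking ties.

The search works with exact residue masses; residues that the working
tolerance cannot separate are collapsed only in the reported sequence, as
ambiguity classes: Ile/Leu are exactly isobaric (reported as 'J'); at 0.2 Da
Lys/Gln also collapse (reported as '[K/Q]').
"""

from __future__ import annotations

import itertools
import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .masscalc import (
    ACID_TERM,
    AMIDE_TERM,
    A_MINUS_B,
    HYDROGEN,
    IMMONIUM_OFFSET,
    CTerm,
    InputError,
    IonType,
    RESIDUE_MASSES,
)
from .spectra import MatchTolerance, Peak, Spectrum

__all__ = [
    "AmbiguityClass",
    "build_ambiguity_classes",
    "canonical_labels",
    "equivalent_terminal_readings",
    "SeriesStep",
    "IonSeries",
    "SequenceCandidate",
    "DenovoConfig",
    "seed_candidates",
    "extend_series",
    "denovo_sequence",
]

logger = logging.getLogger(__name__)

_STANDARD_RESIDUES = [aa for aa in RESIDUE_MASSES if aa != "J"]


@dataclass(frozen=True, eq=False)
class AmbiguityClass:
    """A set of residues indistinguishable at the active mass tolerance."""

    label: str
    members: frozenset[str]
    mass: float

    def __eq__(self, other) -> bool:
        return isinstance(other, AmbiguityClass) and self.label == other.label

    def __hash__(self) -> int:
        return hash(self.label)

    def __repr__(self) -> str:  # compact in candidate dumps
        return f"AmbiguityClass({self.label}, {self.mass:.5f})"


def build_ambiguity_classes(tol: MatchTolerance) -> list[AmbiguityClass]:
    """Collapse the standard residues into classes at the given tolerance.

    Residues are clustered so that every member lies within the window of the
    class mass (the member mean). The Ile/Leu class is labelled 'J'; other
    multi-member classes list their members, e.g. '[K/Q]' (which appears at
    0.2 Da but not at 0.01 Da).
    """
    ordered = sorted(_STANDARD_RESIDUES, key=lambda aa: (RESIDUE_MASSES[aa], aa))
    classes: list[AmbiguityClass] = []
    group: list[str] = []

    def flush() -> None:
        if not group:
            return
        masses = [RESIDUE_MASSES[aa] for aa in group]
        classes.append(
            AmbiguityClass(_class_label(group), frozenset(group), sum(masses) / len(masses))
        )

    for aa in ordered:
        if group:
            masses = [RESIDUE_MASSES[x] for x in group] + [RESIDUE_MASSES[aa]]
            center = sum(masses) / len(masses)
            if all(abs(m - center) <= tol.window for m in masses):
                group.append(aa)
                continue
            flush()
            group = []
        group = group + [aa]
    flush()
    return sorted(classes, key=lambda c: c.mass)


def _class_label(members) -> str:
    members = sorted(set(members))
    if set(members) == {"I", "L"}:
        return "J"
    if len(members) == 1:
        return members[0]
    return "[" + "/".join(members) + "]"


def _search_classes() -> list[AmbiguityClass]:
    """Exact-mass residue classes used inside the search.

    Only residues with identical monoisotopic mass share a class (Ile/Leu as
    'J'); near-isobars like Lys/Gln stay separate so every candidate carries
    exact masses, and are merged into tolerance-level ambiguity classes only
    when candidates are reported.
    """
    by_mass: dict[float, list[str]] = {}
    for aa in _STANDARD_RESIDUES:
        by_mass.setdefault(RESIDUE_MASSES[aa], []).append(aa)
    return sorted(
        (
            AmbiguityClass(_class_label(members), frozenset(members), mass)
            for mass, members in by_mass.items()
        ),
        key=lambda c: c.mass,
    )


def canonical_labels(sequence: str, classes: Sequence[AmbiguityClass]) -> str:
    """Rewrite a residue string in the canonical labels of the given classes."""
    by_member = {m: c for c in classes for m in c.members}
    by_member["J"] = by_member["I"]
    return "".join(by_member[aa].label for aa in sequence)


def equivalent_terminal_readings(
    sequence: str, c_term: CTerm, classes: Sequence[AmbiguityClass]
) -> set[tuple[str, CTerm]]:
    """Canonical readings indistinguishable from a peptide by fragment masses.

    A C-terminal Asn free acid has exactly the elemental composition of a
    C-terminal Asp amide (the amide sits on the side chain instead of the
    backbone), and likewise Gln-acid / Glu-amide: every backbone fragment of
    the two readings has the identical mass, at any tolerance. Both readings
    are therefore returned as acceptable interpretations of such a peptide.
    """
    out = {(canonical_labels(sequence, classes), CTerm(c_term))}
    swaps = {
        (CTerm.acid, "N"): ("D", CTerm.amide),
        (CTerm.acid, "Q"): ("E", CTerm.amide),
        (CTerm.amide, "D"): ("N", CTerm.acid),
        (CTerm.amide, "E"): ("Q", CTerm.acid),
    }
    key = (CTerm(c_term), sequence[-1])
    if key in swaps:
        repl, other_term = swaps[key]
        out.add((canonical_labels(sequence[:-1] + repl, classes), other_term))
    return out


@dataclass(frozen=True)
class SeriesStep:
    """One growth step of an ion series: a residue class, or an unordered
    pair bridging a single missing ion (or the unordered b2 seed pair)."""

    kind: str  # 'res' or 'gap'
    classes: tuple[AmbiguityClass, ...]

    @property
    def mass(self) -> float:
        return sum(c.mass for c in self.classes)

    @property
    def key(self) -> tuple:
        return (self.kind,) + tuple(c.label for c in self.classes)


@dataclass(frozen=True)
class IonSeries:
    """A grown ion series on the cumulative residue-mass axis.

    ``anchors`` are the supporting peaks with their cumulative residue mass
    (b-series: b_k - 1.00782; y-series: y_k minus the terminal constant);
    ``steps`` reads N->C for b series and C->N for y series; ``tail`` holds
    residues inferred from the precursor remainder without a supporting peak.
    """

    series_type: str  # 'b' or 'y'
    c_term: Optional[CTerm]  # known for y series, open for b series
    anchors: tuple[tuple[Optional[Peak], float], ...]
    steps: tuple[SeriesStep, ...]
    tail: tuple[SeriesStep, ...] = ()
    complete: bool = False

    @property
    def cumulative(self) -> float:
        return self.anchors[-1][1] if self.anchors else 0.0


@dataclass(frozen=True)
class SequenceCandidate:
    """A ranked de novo result with per-position residue ambiguity classes."""

    classes: tuple[AmbiguityClass, ...]
    c_term: CTerm
    score: float
    matched_ions: int
    gaps: tuple[tuple[int, int], ...] = ()  # residue spans read as unordered pairs
    mean_match_error: float = 0.0  # mean |observed - theoretical| of matched ions, Da

    @property
    def canonical(self) -> str:
        return "".join(c.label for c in self.classes)

    @property
    def masses(self) -> tuple[float, ...]:
        return tuple(c.mass for c in self.classes)

    @property
    def mh(self) -> float:
        term = AMIDE_TERM if self.c_term is CTerm.amide else ACID_TERM
        return sum(self.masses) + term


@dataclass(frozen=True)
class DenovoConfig:
    """Search-size knobs; defaults keep the search deterministic and bounded."""

    live_cap: int = 300  # live series kept per extension round
    tip_cap: int = 3  # live series kept per distinct cumulative mass
    rescore_cap: int = 500  # candidates re-scored against the full ion set
    max_orderings: int = 32  # orderings expanded per gapped series
    max_gaps: int = 3  # bridged missing-ion gaps allowed per series
    score_ion_types: frozenset = frozenset(
        {IonType.a, IonType.b, IonType.y, IonType.internal_b, IonType.immonium}
    )


class _ClassTable:
    """Sorted-mass lookup tables for residue classes and class pairs."""

    def __init__(self, classes: Sequence[AmbiguityClass], window: float):
        self.classes = sorted(classes, key=lambda c: (c.mass, c.label))
        self.class_masses = [c.mass for c in self.classes]
        pairs = []
        for i, a in enumerate(self.classes):
            for b in self.classes[i:]:
                pairs.append((a.mass + b.mass, (a, b)))
        pairs.sort(key=lambda t: (t[0], t[1][0].label, t[1][1].label))
        self.pair_sums = [s for s, _ in pairs]
        self.pairs = [p for _, p in pairs]
        self.window = window
        self.min_step = self.class_masses[0] - window
        self.max_step = self.pair_sums[-1] + window

    def singles(self, delta: float) -> list[AmbiguityClass]:
        lo = bisect_left(self.class_masses, delta - self.window)
        hi = bisect_right(self.class_masses, delta + self.window)
        return self.classes[lo:hi]

    def doubles(self, delta: float) -> list[tuple[AmbiguityClass, AmbiguityClass]]:
        lo = bisect_left(self.pair_sums, delta - self.window)
        hi = bisect_right(self.pair_sums, delta + self.window)
        return self.pairs[lo:hi]


def seed_candidates(spectrum: Spectrum, tol: MatchTolerance = MatchTolerance()):
    """Find candidate b2 and y1 seed ions in an MS/MS spectrum.

    b2 candidates are peaks whose m/z minus 1.00782 matches the summed mass of
    some residue pair; y1 candidates are peaks matching a residue plus the
    amide (18.03437) or free-acid (19.01839) terminal constant. Both terminus
    hypotheses are carried. Empty seed lists are a valid outcome.
    """
    if spectrum.ms_level != 2 or spectrum.precursor_mh is None:
        raise InputError("seeding requires an MS/MS spectrum with precursor_mh")
    table = _ClassTable(_search_classes(), tol.window)
    b2: list[tuple[Peak, list[tuple[AmbiguityClass, AmbiguityClass]]]] = []
    y1: list[tuple[Peak, AmbiguityClass, CTerm]] = []
    for peak in spectrum.peaks:
        hit_pairs = table.doubles(peak.mz - HYDROGEN)
        if hit_pairs:
            b2.append((peak, hit_pairs))
        for term_const, c_term in ((AMIDE_TERM, CTerm.amide), (ACID_TERM, CTerm.acid)):
            for cls in table.singles(peak.mz - term_const):
                y1.append((peak, cls, c_term))
    return b2, y1


@dataclass(frozen=True)
class _Node:
    """A live series during extension, on the cumulative residue-mass axis.

    ``offset`` converts a peak m/z into its axis value (axis = mz - offset):
    1.00782 for b series, the terminal constant for y series. ``skey`` is the
    accumulated step-identity tuple used for cheap deduplication.
    """

    tip: float
    offset: float
    steps: tuple[SeriesStep, ...]
    anchors: tuple[tuple[Optional[Peak], float], ...]
    intensity: float
    error: float = 0.0  # cumulative |observed - class| mass error, Da
    n_gaps: int = 0  # bridged missing-ion gaps (the b2 seed pair not counted)
    support: float = 0.0  # anchor intensity plus complementary-ion intensity
    skey: tuple = ()


def _extend(
    spectrum: Spectrum,
    roots: Sequence[_Node],
    table: _ClassTable,
    targets: Sequence[tuple[float, CTerm]],
    config: DenovoConfig,
    collector: dict,
    direction_is_y: bool,
    precursor_mh: float,
) -> Optional[_Node]:
    """Grow series depth-synchronously from the given roots.

    At each step the mass difference to a further peak is read as a single
    residue class when one fits, otherwise as an unordered residue pair
    bridging one missing ion (a difference a single residue explains is never
    also read as a dipeptide). A series completes when the remaining mass to a
    precursor target is zero, one residue, or one unordered pair; completions
    are deduplicated into ``collector`` keyed by their step sequence. Returns
    the longest partial series for diagnostics.
    """
    mz_list = [p.mz for p in spectrum.peaks]
    window = table.window
    max_target = max(t for t, _ in targets)
    partial_best: Optional[_Node] = None

    def complement_intensity(mz: float) -> float:
        # b/y complementarity: b_k + y_{n-k} = MH+ + 1.00782; a peak with a
        # complementary partner is corroborated by the opposite ion series
        comp = precursor_mh + HYDROGEN - mz
        lo = bisect_left(mz_list, comp - 2 * window)
        hi = bisect_right(mz_list, comp + 2 * window)
        return max((p.intensity for p in spectrum.peaks[lo:hi]), default=0.0)

    def check(node: _Node) -> None:
        nonlocal partial_best
        if partial_best is None or len(node.steps) > len(partial_best.steps):
            partial_best = node
        for target, c_term in targets:
            r = target - node.tip
            if abs(r) <= window:
                _collect(collector, node, (), abs(r), c_term, direction_is_y)
                continue
            if r < table.min_step:
                continue
            singles = table.singles(r)
            if singles:
                for cls in singles:
                    _collect(
                        collector, node, (SeriesStep("res", (cls,)),),
                        abs(r - cls.mass), c_term, direction_is_y,
                    )
            elif node.n_gaps < config.max_gaps:
                for pair in table.doubles(r):
                    _collect(
                        collector, node, (SeriesStep("gap", pair),),
                        abs(r - pair[0].mass - pair[1].mass), c_term, direction_is_y,
                    )

    frontier = list(roots)
    for node in frontier:
        check(node)
    while frontier:
        nxt: list[_Node] = []
        for node in frontier:
            lo = bisect_left(mz_list, node.tip + node.offset + table.min_step)
            hi = bisect_right(mz_list, node.tip + node.offset + table.max_step)
            for peak in spectrum.peaks[lo:hi]:
                axis = peak.mz - node.offset
                if axis > max_target + window:
                    continue
                delta = axis - node.tip
                singles = table.singles(delta)
                if singles:
                    branches = [SeriesStep("res", (c,)) for c in singles]
                elif node.n_gaps < config.max_gaps:
                    branches = [SeriesStep("gap", p) for p in table.doubles(delta)]
                else:
                    branches = []
                if branches:
                    gain = peak.intensity + complement_intensity(peak.mz)
                for step in branches:
                    nxt.append(
                        _Node(
                            axis,
                            node.offset,
                            node.steps + (step,),
                            node.anchors + ((peak, axis),),
                            node.intensity + peak.intensity,
                            node.error + abs(delta - step.mass),
                            node.n_gaps + (1 if step.kind == "gap" else 0),
                            node.support + gain,
                            node.skey + (step.key,),
                        )
                    )
        for node in nxt:
            check(node)
        if len(nxt) > config.live_cap:
            # keep the best-supported series, but at most tip_cap per distinct
            # cumulative mass: noise-peak detours that rejoin the true ladder
            # would otherwise multiply into families that flood the frontier
            nxt.sort(key=lambda n: (-n.support, n.error, n.tip, n.skey))
            kept: list[_Node] = []
            per_tip: dict[float, int] = {}
            for node in nxt:
                t = round(node.tip, 2)
                c = per_tip.get(t, 0)
                if c < config.tip_cap:
                    per_tip[t] = c + 1
                    kept.append(node)
                    if len(kept) >= config.live_cap:
                        break
            nxt = kept
        frontier = nxt
    return partial_best


def _collect(collector, node, tail, tail_error, c_term, direction_is_y) -> None:
    key = (node.skey + tuple(s.key for s in tail), c_term, direction_is_y)
    prev = collector.get(key)
    if prev is None or (-node.support, node.error + tail_error) < (-prev[0], prev[1]):
        collector[key] = (
            node.support,
            node.error + tail_error,
            node.steps + tail,
            c_term,
            direction_is_y,
            node,
            tail,
        )


def _make_root(axis, offset, steps, anchors, intensity) -> _Node:
    return _Node(
        axis,
        offset,
        steps,
        anchors,
        intensity,
        skey=tuple(s.key for s in steps),
    )


def _b_targets(precursor_mh: float) -> list[tuple[float, CTerm]]:
    return [
        (precursor_mh - AMIDE_TERM, CTerm.amide),
        (precursor_mh - ACID_TERM, CTerm.acid),
    ]


def extend_series(
    spectrum: Spectrum,
    seed,
    series_type: str,
    tol: MatchTolerance = MatchTolerance(),
    config: DenovoConfig = DenovoConfig(),
) -> list[IonSeries]:
    """Grow one seed into ion series by reading peak-to-peak mass differences.

    ``seed`` is one element of the corresponding ``seed_candidates`` list:
    ``(peak, pair_list)`` for a b2 seed, ``(peak, residue_class, c_term)`` for
    a y1 seed. Returns completed series plus the longest partial (retained
    even at zero growth).
    """
    if series_type not in ("b", "y"):
        raise InputError(f"series_type must be 'b' or 'y', got {series_type!r}")
    if spectrum.precursor_mh is None:
        raise InputError("extension requires a declared precursor MH+")
    table = _ClassTable(_search_classes(), tol.window)
    if series_type == "b":
        peak, pair_list = seed
        axis = peak.mz - HYDROGEN
        roots = [
            _make_root(axis, HYDROGEN, (SeriesStep("gap", p),), ((peak, axis),), peak.intensity)
            for p in pair_list
        ]
        targets = _b_targets(spectrum.precursor_mh)
        seed_c_term = None
        is_y = False
    else:
        peak, cls, seed_c_term = seed
        term = AMIDE_TERM if seed_c_term is CTerm.amide else ACID_TERM
        axis = peak.mz - term
        roots = [
            _make_root(axis, term, (SeriesStep("res", (cls,)),), ((peak, axis),), peak.intensity)
        ]
        targets = [(spectrum.precursor_mh - term, seed_c_term)]
        is_y = True
    collector: dict = {}
    partial = _extend(
        spectrum, roots, table, targets, config, collector, is_y, spectrum.precursor_mh
    )
    series = [
        IonSeries(series_type, c_term, node.anchors, node.steps, tail, complete=True)
        for _, _, _, c_term, _, node, tail in collector.values()
    ]
    if partial is not None:
        series.append(
            IonSeries(series_type, seed_c_term, partial.anchors, partial.steps, (), complete=False)
        )
    return series


def _expand_orderings(
    steps: Sequence[SeriesStep], reverse: bool, cap: int
) -> tuple[list[tuple[str, ...]], tuple[tuple[int, int], ...]]:
    """Expand gap pairs into explicit residue orders (both orders per gap).

    Returns (label sequences, gap spans) in final N->C numbering; ``reverse``
    flips a C->N (y-series) reading. Gap spans do not depend on the chosen
    order and are shared by all expansions; the number of orderings is capped
    deterministically.
    """
    options: list[list[tuple[str, ...]]] = []
    n_combos = 1
    spans: list[tuple[int, int]] = []
    pos = 1
    for step in steps:
        labels = tuple(c.label for c in step.classes)
        if step.kind == "res" or labels[0] == labels[1]:
            options.append([labels])
        else:
            options.append([labels, labels[::-1]])
            n_combos *= 2
        if step.kind == "gap":
            spans.append((pos, pos + len(labels) - 1))
        pos += len(labels)
    n = pos - 1
    if reverse:
        spans = [(n - j + 1, n - i + 1) for i, j in spans]
    combos = (
        [tuple(o[0] for o in options)]
        if n_combos == 1
        else itertools.islice(itertools.product(*options), cap)
    )
    out = []
    for combo in combos:
        flat = tuple(label for part in combo for label in part)
        out.append(flat[::-1] if reverse else flat)
    return out, tuple(sorted(spans))


def _score_masses(
    mz_arr: np.ndarray,
    int_arr: np.ndarray,
    tic: float,
    masses: Sequence[float],
    c_term: CTerm,
    window: float,
    ion_types: frozenset,
) -> tuple[float, int, int, float]:
    """Explained-intensity score against the theoretical ion set (vectorized).

    Returns (fraction of total ion current explained by matched ions in [0,1],
    number of theoretical ions matched, size of the theoretical set, and the
    mean absolute m/z error of matched ions -- the mass-accuracy signal that
    separates near-isobaric readings which all fall inside the window).
    """
    m = np.asarray(masses, dtype=float)
    n = len(m)
    prefix = np.cumsum(m)
    term = AMIDE_TERM if c_term is CTerm.amide else ACID_TERM
    frags: list[np.ndarray] = []
    if IonType.b in ion_types and n > 1:
        frags.append(prefix[:-1] + HYDROGEN)
    if IonType.a in ion_types and n > 1:
        frags.append(prefix[:-1] + HYDROGEN - A_MINUS_B)
    if IonType.y in ion_types and n > 1:
        frags.append(prefix[-1] - prefix[:-1] + term)
    if IonType.internal_b in ion_types or IonType.internal_a in ion_types:
        for i in range(2, n):  # spans i..j, j in i+1..n-1
            seg = prefix[i : n - 1] - prefix[i - 2] + HYDROGEN
            if len(seg) == 0:
                continue
            if IonType.internal_b in ion_types:
                frags.append(seg)
            if IonType.internal_a in ion_types:
                frags.append(seg - A_MINUS_B)
    if IonType.immonium in ion_types:
        frags.append(m - IMMONIUM_OFFSET)
    if IonType.precursor in ion_types:
        frags.append(np.array([prefix[-1] + term]))
    if not frags:
        return 0.0, 0, 0, 0.0
    theo = np.concatenate(frags)
    lo = np.searchsorted(mz_arr, theo - window)
    hi = np.searchsorted(mz_arr, theo + window, side="right")
    hit = hi > lo
    matched_ions = int(hit.sum())
    idx: set[int] = set()
    err_sum = 0.0
    for t, l, h in zip(theo[hit], lo[hit], hi[hit]):
        idx.update(range(int(l), int(h)))
        err_sum += min(abs(mz_arr[i] - t) for i in range(int(l), int(h)))
    mean_err = err_sum / matched_ions if matched_ions else 0.0
    if tic <= 0 or not idx:
        return 0.0, matched_ions, len(theo), mean_err
    return (
        min(float(int_arr[sorted(idx)].sum()) / tic, 1.0),
        matched_ions,
        len(theo),
        mean_err,
    )


_BY_ONLY = frozenset({IonType.b, IonType.y})

#: TIC-fraction penalty per Da of mean backbone mass error in candidate
#: ranking (10 means 0.01 Da of systematic ladder offset cancels a 10%-of-TIC
#: explained-intensity advantage).
_ERR_WEIGHT = 10.0


def _backbone_prescore(entries, mass_by_label, mz_arr: np.ndarray, window: float) -> np.ndarray:
    """Matched fraction and mean error of each candidate's b/y ladder.

    Vectorized over candidates (batched by length and terminus) so the whole
    unique-candidate set can be triaged before the full ion-set rescoring.
    Returns an (n, 2) array of (backbone fraction matched, mean |error|).
    """
    out = np.zeros((len(entries), 2))
    groups: dict[tuple[int, CTerm], list[int]] = {}
    for idx, entry in enumerate(entries):
        groups.setdefault((len(entry[2]), entry[3]), []).append(idx)
    n_peaks = len(mz_arr)
    for (n, c_term), idxs in groups.items():
        if n < 2:
            continue
        masses = np.array(
            [[mass_by_label[l] for l in entries[i][2]] for i in idxs]
        )
        prefix = np.cumsum(masses, axis=1)
        term = AMIDE_TERM if c_term is CTerm.amide else ACID_TERM
        b_ions = prefix[:, :-1] + HYDROGEN
        y_ions = (prefix[:, -1:] - prefix[:, :-1]) + term
        theo = np.concatenate([b_ions, y_ions], axis=1)
        flat = theo.ravel()
        pos = np.searchsorted(mz_arr, flat)
        left = np.clip(pos - 1, 0, n_peaks - 1)
        right = np.clip(pos, 0, n_peaks - 1)
        dist = np.minimum(np.abs(mz_arr[left] - flat), np.abs(mz_arr[right] - flat))
        hit = (dist <= window).reshape(theo.shape)
        dist = np.where(hit, dist.reshape(theo.shape), 0.0)
        counts = hit.sum(axis=1)
        frac = counts / theo.shape[1]
        err = np.where(counts > 0, dist.sum(axis=1) / np.maximum(counts, 1), 0.0)
        for j, i in enumerate(idxs):
            out[i] = (frac[j], err[j])
    return out


def denovo_sequence(
    spectrum: Spectrum,
    tol: MatchTolerance = MatchTolerance(),
    config: DenovoConfig = DenovoConfig(),
) -> list[SequenceCandidate]:
    """De novo sequence an MS/MS spectrum; returns ranked sequence candidates.

    Candidate b2/y1 seeds are grown in both directions; when no seed exists,
    exhaustive extension starts from zero cumulative mass. Completed series
    are expanded into explicit residue orders, deduplicated up to ambiguity
    classes, checked for precursor-mass soundness, re-scored by the fraction
    of total ion current explained by their full theoretical ion set, and
    ranked by score, then backbone-series completeness and mass accuracy,
    then the same over the full ion set, then canonical label.
    """
    if spectrum.ms_level != 2 or spectrum.precursor_mh is None:
        raise InputError("de novo sequencing requires MS/MS with precursor_mh")
    if not spectrum.peaks:
        return []
    pmh = spectrum.precursor_mh
    table = _ClassTable(_search_classes(), tol.window)
    report_classes = build_ambiguity_classes(tol)
    report_by_member = {m: c for c in report_classes for m in c.members}
    report_by_search_label = {
        c.label: report_by_member[next(iter(c.members))] for c in table.classes
    }
    b2_seeds, y1_seeds = seed_candidates(spectrum, tol)

    runs: list[tuple[list[_Node], list[tuple[float, CTerm]], bool]] = []
    b_roots: list[_Node] = []
    for peak, pair_list in b2_seeds:
        axis = peak.mz - HYDROGEN
        for p in pair_list:
            b_roots.append(
                _make_root(axis, HYDROGEN, (SeriesStep("gap", p),), ((peak, axis),), peak.intensity)
            )
    if b_roots:
        runs.append((b_roots, _b_targets(pmh), False))
    y_roots: dict[CTerm, list[_Node]] = {CTerm.amide: [], CTerm.acid: []}
    for peak, cls, c_term in y1_seeds:
        term = AMIDE_TERM if c_term is CTerm.amide else ACID_TERM
        axis = peak.mz - term
        y_roots[c_term].append(
            _make_root(axis, term, (SeriesStep("res", (cls,)),), ((peak, axis),), peak.intensity)
        )
    for c_term, roots in y_roots.items():
        if roots:
            term = AMIDE_TERM if c_term is CTerm.amide else ACID_TERM
            runs.append((roots, [(pmh - term, c_term)], True))
    # zero-mass roots run alongside the seeds: they rescue a direction whose
    # seeding ion (b2 or y1) went undetected, and are the whole search when no
    # seed exists at all
    runs.append(([_make_root(0.0, HYDROGEN, (), (), 0.0)], _b_targets(pmh), False))
    for c_term, term in ((CTerm.amide, AMIDE_TERM), (CTerm.acid, ACID_TERM)):
        runs.append(
            ([_make_root(0.0, term, (), (), 0.0)], [(pmh - term, c_term)], True)
        )

    collector: dict = {}
    longest_partial: Optional[_Node] = None
    # the zero-mass rescue runs carry a reduced beam: they only need to
    # recover a mostly intact, well-supported ladder whose seed ion is absent
    rescue_config = (
        config
        if not (b_roots or y1_seeds)
        else DenovoConfig(
            live_cap=max(config.live_cap // 3, 50),
            tip_cap=config.tip_cap,
            rescore_cap=config.rescore_cap,
            max_orderings=config.max_orderings,
            max_gaps=config.max_gaps,
            score_ion_types=config.score_ion_types,
        )
    )
    for roots, targets, is_y in runs:
        run_config = rescue_config if roots[0].tip == 0.0 else config
        partial = _extend(spectrum, roots, table, targets, run_config, collector, is_y, pmh)
        if partial is not None and (
            longest_partial is None or len(partial.steps) > len(longest_partial.steps)
        ):
            longest_partial = partial

    if not collector:
        if longest_partial is not None:
            logger.warning(
                "no candidate reached the precursor mass; longest partial series "
                "has %d steps ending at cumulative mass %.4f",
                len(longest_partial.steps),
                longest_partial.tip,
            )
        return []

    # expand gap orderings; deduplicate exact residue readings, remembering
    # the best-supported, mass-closest series per reading
    term_const = {CTerm.amide: AMIDE_TERM, CTerm.acid: ACID_TERM}
    mass_by_label = {c.label: c.mass for c in table.classes}
    unique: dict[tuple, tuple[float, float, tuple]] = {}
    for support, error, steps, c_term, is_y, _, _ in collector.values():
        total = sum(s.mass for s in steps) + term_const[c_term]
        if abs(total - pmh) > tol.window:
            continue  # soundness: candidate must account for the precursor
        labels_list, gap_spans = _expand_orderings(steps, is_y, config.max_orderings)
        for labels in labels_list:
            key = (labels, c_term)
            prev = unique.get(key)
            if prev is None or (-support, error) < (-prev[0], prev[1]):
                unique[key] = (support, error, gap_spans)

    entries = sorted(
        (
            (support, err, key[0], key[1], spans)
            for key, (support, err, spans) in unique.items()
        ),
        key=lambda e: (-e[0], e[1], e[2], e[3].value),
    )
    mz_arr = spectrum.mz
    int_arr = spectrum.intensity
    tic = float(int_arr.sum())
    if len(entries) > config.rescore_cap:
        # cheap vectorized backbone-series prescore selects what is worth the
        # full ion-set rescoring: candidates whose own b/y ladder is complete
        # and mass-accurate come first, regardless of search-path support
        pre = _backbone_prescore(entries, mass_by_label, mz_arr, tol.window)
        pre_frac = np.round(pre[:, 0], 6)
        pre_err = np.round(pre[:, 1], 4)
        order = sorted(
            range(len(entries)),
            key=lambda i: (
                -pre_frac[i],
                pre_err[i],
                -entries[i][0],
                entries[i][2],
                entries[i][3].value,
            ),
        )
        entries = [entries[i] for i in order[: config.rescore_cap]]

    scored = []
    for _, _, labels, c_term, gap_spans in entries:
        masses = [mass_by_label[l] for l in labels]
        score, matched, n_theo, mean_err = _score_masses(
            mz_arr, int_arr, tic, masses, c_term, tol.window, config.score_ion_types
        )
        _, m_by, n_by, err_by = _score_masses(
            mz_arr, int_arr, tic, masses, c_term, tol.window, _BY_ONLY
        )
        frac_by = m_by / n_by if n_by else 0.0
        frac = matched / n_theo if n_theo else 0.0
        # primary quality: explained intensity penalized by systematic
        # backbone mass error (0.01 Da of mean b/y error outweighs an extra
        # 10% of explained TIC: on a calibrated TOF/TOF a systematic ladder
        # offset is strong evidence against a reading, while a small
        # explained-intensity edge is usually one coincidental noise peak);
        # binned at 1% so residual noise-level differences fall to the
        # structural tie-breaks
        quality = round(score - _ERR_WEIGHT * err_by, 2)
        tail = (
            -round(frac_by, 6),
            round(err_by, 4),
            -round(frac, 6),
            round(mean_err, 4),
        )
        report_seq = tuple(report_by_search_label[l] for l in labels)
        scored.append(
            (
                (-quality,) + tail,
                SequenceCandidate(report_seq, c_term, score, matched, gap_spans, mean_err),
            )
        )
    # rank: error-penalized explained intensity, then backbone-series
    # completeness and mass accuracy, then the full-ion-set equivalents,
    # then canonical label
    scored.sort(key=lambda t: t[0] + (t[1].canonical, t[1].c_term.value))
    # reporting-level class collapse can alias readings; keep the best of each
    seen: set[tuple[str, CTerm]] = set()
    out: list[SequenceCandidate] = []
    for _, cand in scored:
        key = (cand.canonical, cand.c_term)
        if key not in seen:
            seen.add(key)
            out.append(cand)
    return out
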