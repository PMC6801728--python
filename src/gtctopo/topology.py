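"""Consensus hydropathy profiling, TM segmentation and topology orientation.

GT-C glycosyltransferases are polytopic ER membrane proteins whose helices
(~18-25 residues) show up as sustained hydrophobic runs in a Kyte-Doolittle
profile averaged over a family alignment.  The pipeline:

1. per-reference-position mean hydropathy over the family, smoothed with a
   centred sliding window;
2. thresholded run segmentation with a splitting rule for over-long
   hydrophobic runs (two helices fused into one run, as happens for the
   STT3 helix-5/6 region);
3. orientation by the positive-inside rule (Lys/Arg enrichment of
   cytoplasm-facing loops), overridden by a C-terminal dilysine
   ER-retrieval signal, which must face the cytoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .seqio import AlignedFamily

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

SCALE_MIN = min(KYTE_DOOLITTLE.values())
SCALE_MAX = max(KYTE_DOOLITTLE.values())

Side = Literal["cytoplasmic", "luminal"]


def _other(side: Side) -> Side:
    return "luminal" if side == "cytoplasmic" else "cytoplasmic"


@dataclass(frozen=True)
class HydropathyProfile:
    """Per-reference-position consensus hydropathy (1-based positions)."""

    raw: np.ndarray
    smoothed: np.ndarray
    coverage: np.ndarray
    window: int
    low_coverage: np.ndarray  # bool flags, coverage < 0.5 or empty column

    @property
    def length(self) -> int:
        return len(self.raw)

    def to_frame(self, segments: Optional[Sequence["TMDSegment"]] = None):
        import pandas as pd

        in_tmd = np.zeros(self.length, dtype=bool)
        for s in segments or ():
            in_tmd[s.start - 1 : s.end] = True
        return pd.DataFrame(
            {
                "position": np.arange(1, self.length + 1),
                "raw": self.raw,
                "smoothed": self.smoothed,
                "coverage": self.coverage,
                "low_coverage": self.low_coverage,
                "in_tmd": in_tmd,
            }
        )


@dataclass(frozen=True)
class TMDSegment:
    """One membrane-spanning helix, 1-based inclusive reference coordinates."""

    index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.index}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Loop:
    """An inter-helix interval (or terminus) with its membrane side."""

    label: str          # "N-term", "C-term", or loop index between helices
    start: int          # 1-based inclusive; start > end encodes an empty loop
    end: int
    side: Side

    @property
    def length(self) -> int:
        return max(0, self.end - self.start + 1)


@dataclass(frozen=True)
class TopologyModel:
    """Ordered helices plus alternating loop sides over a reference length."""

    segments: tuple[TMDSegment, ...]
    n_term_side: Side
    length: int
    decided_by: str = "positive-inside"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("topology model requires at least one segment")
        prev_end = 0
        for s in self.segments:
            if s.start <= prev_end:
                raise ValueError("segments overlap or are unsorted")
            prev_end = s.end
        if prev_end > self.length:
            raise ValueError("segments extend beyond reference length")

    @property
    def n_tmds(self) -> int:
        return len(self.segments)

    @property
    def c_term_side(self) -> Side:
        side = self.n_term_side
        for _ in self.segments:
            side = _other(side)
        return side

    def loops(self) -> list[Loop]:
        """All loop intervals, N-terminal tail first, with alternating sides.

        Empty intervals (adjacent helices) are included with zero length so
        loop numbering stays aligned with helix indices.
        """
        out: list[Loop] = []
        side = self.n_term_side
        segs = self.segments
        out.append(Loop("N-term", 1, segs[0].start - 1, side))
        for a, b in zip(segs, segs[1:]):
            side = _other(side)
            out.append(Loop(f"loop{a.index}-{b.index}", a.end + 1, b.start - 1, side))
        out.append(Loop("C-term", segs[-1].end + 1, self.length, _other(side)))
        return out

    def labelled_loops(self) -> list[tuple[str, Loop]]:
        """Loops with field-style names: luminal inter-helix loops EL1.. in
        N->C order, cytoplasmic ones CL1..; termini keep N-term/C-term."""
        out: list[tuple[str, Loop]] = []
        counters = {"luminal": 0, "cytoplasmic": 0}
        for lp in self.loops():
            if lp.label in ("N-term", "C-term"):
                out.append((lp.label, lp))
            else:
                counters[lp.side] += 1
                prefix = "EL" if lp.side == "luminal" else "CL"
                out.append((f"{prefix}{counters[lp.side]}", lp))
        return out

    def side_mask(self) -> dict[Side, np.ndarray]:
        """Boolean position masks (length L) for each side's loop residues."""
        masks = {
            "cytoplasmic": np.zeros(self.length, dtype=bool),
            "luminal": np.zeros(self.length, dtype=bool),
        }
        for lp in self.loops():
            if lp.length:
                masks[lp.side][lp.start - 1 : lp.end] = True
        return masks

    def segments_table(self, reference_name: str = "ref"):
        """BED-like table: 0-based half-open start, 1-based end, helix index."""
        import pandas as pd

        return pd.DataFrame(
            {
                "reference": reference_name,
                "start0": [s.start - 1 for s in self.segments],
                "end": [s.end for s in self.segments],
                "helix": [s.index for s in self.segments],
            }
        )


# ---------------------------------------------------------------------------
# profile


def hydropathy_profile(family: AlignedFamily, window: int = 19) -> HydropathyProfile:
    """Consensus Kyte-Doolittle profile on reference coordinates.

    ``raw[p]`` is the mean scale value over non-gap, non-X residues of
    column ``p``; empty columns are imputed at the scale minimum and
    flagged.  ``smoothed`` is a centred moving average whose window shrinks
    symmetrically at the termini.  The family must already be degapped to
    its reference.
    """
    if window % 2 == 0 or window < 5:
        raise ValueError("window must be odd and >= 5")
    if family.reference_id is None:
        raise RuntimeError("reference not set")
    L = family.length
    n = family.n
    raw = np.empty(L)
    coverage = np.empty(L)
    empty = np.zeros(L, dtype=bool)
    for c in range(L):
        col = family.column(c)
        vals = [KYTE_DOOLITTLE[a] for a in col if a in KYTE_DOOLITTLE]
        coverage[c] = sum(1 for a in col if a != "-") / n
        if vals:
            raw[c] = float(np.mean(vals))
        else:
            raw[c] = SCALE_MIN
            empty[c] = True
    half = window // 2
    smoothed = np.empty(L)
    for c in range(L):
        # shrink symmetrically near the termini to keep the window centred
        h = min(half, c, L - 1 - c)
        smoothed[c] = raw[c - h : c + h + 1].mean()
    low = (coverage < 0.5) | empty
    return HydropathyProfile(
        raw=raw, smoothed=smoothed, coverage=coverage, window=window, low_coverage=low
    )


# ---------------------------------------------------------------------------
# segmentation


def _split_run(
    smoothed: np.ndarray, start: int, end: int, min_tm: int, max_tm: int
) -> list[tuple[int, int]]:
    """Split a 1-based inclusive run recursively at interior hydropathy minima.

    The split point is the smoothed-hydropathy minimum inside the run,
    excluding ``min_tm``-sized margins at both ends (leftmost on ties); the
    minimum position itself becomes a one-residue loop.  Runs too short to
    admit a split point are emitted unsplit.
    """
    length = end - start + 1
    if length <= max_tm:
        return [(start, end)]
    lo, hi = start + min_tm, end - min_tm  # candidate split positions
    if lo > hi:
        return [(start, end)]
    window = smoothed[lo - 1 : hi]
    m = lo + int(np.argmin(window))
    left = _split_run(smoothed, start, m - 1, min_tm, max_tm)
    right = _split_run(smoothed, m + 1, end, min_tm, max_tm)
    return left + right


def segment_tmds(
    profile: HydropathyProfile,
    threshold: float = 1.5,
    min_tm: int = 15,
    max_tm: int = 28,
    merge_gap: int = 0,
) -> list[TMDSegment]:
    """Segment the smoothed profile into TM helices.

    Maximal runs with smoothed hydropathy >= threshold become helices; runs
    separated by a sub-threshold dip of at most ``merge_gap`` positions are
    fused first; runs shorter than ``min_tm`` are discarded and runs longer
    than ``max_tm`` are split at interior hydropathy minima (two fused
    helices).
    """
    if min_tm >= max_tm:
        raise ValueError("min_tm must be < max_tm")
    runs = _threshold_runs(profile.smoothed, threshold)
    if merge_gap:
        runs = _merge_runs(runs, merge_gap)
    segments: list[tuple[int, int]] = []
    for s, e in runs:
        if e - s + 1 >= min_tm:
            segments.extend(_split_run(profile.smoothed, s, e, min_tm, max_tm))
    return [TMDSegment(index=i + 1, start=s, end=e) for i, (s, e) in enumerate(segments)]


def _threshold_runs(smoothed: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal 1-based inclusive runs with smoothed >= threshold."""
    above = smoothed >= threshold
    runs: list[tuple[int, int]] = []
    c = 0
    L = len(smoothed)
    while c < L:
        if above[c]:
            s = c
            while c < L and above[c]:
                c += 1
            runs.append((s + 1, c))
        else:
            c += 1
    return runs


def _merge_runs(runs: list[tuple[int, int]], gap_max: int) -> list[tuple[int, int]]:
    """Fuse runs separated by short sub-threshold dips (<= gap_max positions).

    Brief dips occur both inside genuine helices (fragmenting their run) and
    at narrow loops; fused runs that exceed max_tm are recovered by the
    splitting rule, so fusing is safe while fragmentation is not.
    """
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 <= gap_max:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _best_split(raw: np.ndarray, lo: int, hi: int, crude: int, direction: int) -> int:
    """Two-mean change-point on raw[lo-1:hi] (1-based bounds).

    Returns the last position of the left part; candidates run from lo to
    hi-1 so both parts are non-empty.  ``direction`` restricts the step:
    +1 demands a rise (loop -> helix, a start edge), -1 a drop (helix ->
    loop, an end edge); without a valid candidate the crude edge stands.
    Ties go to the candidate closest to ``crude`` (then leftmost).
    """
    window = raw[lo - 1 : hi]
    best_t, best_key = crude, (np.inf, np.inf, np.inf)
    for t in range(lo, hi):
        left = window[: t - lo + 1]
        right = window[t - lo + 1 :]
        if direction * (right.mean() - left.mean()) <= 0:
            continue
        sse = float(
            ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        )
        key = (sse, abs(t - crude), t)
        if key < best_key:
            best_key, best_t = key, t
    return best_t


def refine_boundaries(
    segments: Sequence[TMDSegment],
    profile: HydropathyProfile,
    halfwidth: Optional[int] = None,
    min_tm: int = 15,
    max_tm: int = 28,
) -> list[TMDSegment]:
    """Snap helix edges to the raw-profile step between helix and loop levels.

    Threshold-run segmentation places edges where the *smoothed* profile
    crosses a fixed level, which biases them toward the helix interior next
    to strongly hydrophilic (Lys/Arg-rich) loops and toward the loop after a
    run split.  Each edge is re-placed by a local two-level change-point fit
    on the unsmoothed consensus profile, searched within ``halfwidth``
    (default: half the smoothing window) of the crude edge and constrained
    not to cross neighbouring helices.  Edges whose move would push a helix
    outside [min_tm, max_tm] are left at their crude position.
    """
    if not segments:
        return []
    hw = profile.window // 2 if halfwidth is None else halfwidth
    raw = profile.raw
    L = profile.length
    crude = [(s.start, s.end) for s in segments]
    refined: list[list[int]] = [list(c) for c in crude]
    # Alternate start and end passes until no edge moves: each edge search
    # is clamped by its neighbours' current edges, and a neighbour whose
    # own edge was misplaced (typically by an over-long-run split landing
    # inside a helix) unblocks the search only after it has moved itself.
    for _ in range(4):
        moved = False
        # start edges, left to right, bounded by the previous refined end
        for i, (cs, ce) in enumerate(crude):
            prev_end = refined[i - 1][1] if i > 0 else 0
            lo = max(prev_end + 1, cs - hw)
            hi = min(ce, cs + hw)
            if cs > 1 and lo < hi:
                t = _best_split(raw, lo, hi, cs - 1, direction=1)
                if t + 1 != refined[i][0]:
                    refined[i][0] = t + 1
                    moved = True
        # end edges, bounded by the refined start of the next helix
        for i, (cs, ce) in enumerate(crude):
            next_start = refined[i + 1][0] if i + 1 < len(crude) else L + 1
            lo = max(refined[i][0], ce - hw)
            hi = min(next_start - 1, ce + hw + 1)
            if lo < hi and hi <= L:
                t = _best_split(raw, lo, hi, ce, direction=-1)
                if t != refined[i][1]:
                    refined[i][1] = t
                    moved = True
        if not moved:
            break
    out: list[TMDSegment] = []
    for i, (s, e) in enumerate(refined):
        cs, ce = crude[i]
        if not (min_tm <= e - s + 1 <= max_tm):
            s, e = cs, ce  # revert invalid moves
        if out and s <= out[-1].end:
            s = cs  # never overlap the previous refined helix
            if s <= out[-1].end:
                # degenerate: pull the previous end back; crude runs are
                # disjoint, so the previous start always stays below s - 1
                prev = out[-1]
                out[-1] = TMDSegment(index=prev.index, start=prev.start, end=s - 1)
        out.append(TMDSegment(index=len(out) + 1, start=s, end=e))
    return out


def predict_topology(
    family: AlignedFamily,
    window: int = 19,
    threshold: float = 1.5,
    min_tm: int = 15,
    max_tm: int = 28,
    run_min: Optional[int] = None,
) -> tuple[HydropathyProfile, TopologyModel]:
    """Full consensus-topology pipeline: profile, segment, refine, orient.

    Threshold runs are first collected down to ``run_min`` residues
    (default ``min_tm - 6``): a centred window-w smoother turns a helix
    shorter than w into a triangular peak whose above-threshold run is
    narrower than the helix, so genuine 18-residue helices surface as
    13-14-residue runs.  Boundary refinement then snaps edges to the raw
    hydropathy step, and only refined segments of at least ``min_tm``
    residues are kept and renumbered.
    """
    profile = hydropathy_profile(family, window=window)
    if run_min is None:
        run_min = max(5, min_tm - 10)
    runs = segment_tmds(profile, threshold, min_tm=run_min, max_tm=max_tm,
                        merge_gap=3)
    # Refine, then prune sub-min_tm segments one at a time (shortest first)
    # and re-refine the remaining crude runs: a spurious short segment (a
    # split remnant or a hydrophobic loop blip) truncates its neighbours'
    # search windows, so genuine helices can refine short while it is
    # present and must be re-refined once it is gone.
    crude = list(runs)
    while True:
        refined = refine_boundaries(crude, profile, min_tm=min_tm, max_tm=max_tm)
        short = [i for i, s in enumerate(refined) if s.length < min_tm]
        if not short:
            break
        # prune the least helix-like first: a loop-straddling remnant must
        # go before an all-helix fragment, which can still grow to cover
        # its helix once the remnant stops clamping its search window
        def mean_raw(i: int) -> float:
            s = refined[i]
            return float(profile.raw[s.start - 1 : s.end].mean())

        worst = min(short, key=lambda i: (mean_raw(i), refined[i].length, i))
        crude = [
            TMDSegment(index=j + 1, start=s.start, end=s.end)
            for j, s in enumerate(c for i, c in enumerate(crude) if i != worst)
        ]
        if not crude:
            refined = []
            break
    segments = [
        TMDSegment(index=i + 1, start=s.start, end=s.end)
        for i, s in enumerate(refined)
    ]
    if not segments:
        raise RuntimeError("no transmembrane segment found")
    return profile, orient(segments, family)


# ---------------------------------------------------------------------------
# orientation


def _kr_count(reference: str, model: TopologyModel, side: Side) -> int:
    total = 0
    for lp in model.loops():
        if lp.side == side and lp.length:
            total += sum(reference[p - 1] in "KR" for p in range(lp.start, lp.end + 1))
    return total


def orient(
    segments: Sequence[TMDSegment],
    family: AlignedFamily,
) -> TopologyModel:
    """Choose the topology orientation for a segmented reference.

    The positive-inside rule places the orientation's Lys/Arg-richest loop
    set on the cytoplasmic side; ties default to a cytoplasmic N-terminus.
    A C-terminal dilysine ER-retrieval signal on the reference overrides
    the tally: the C-terminus is forced cytoplasmic.
    """
    if not segments:
        raise RuntimeError("cannot orient an empty segmentation")
    if family.reference_id is None:
        raise RuntimeError("reference not set")
    ref = family.reference.ungapped()
    L = len(ref)
    candidates = {
        side: TopologyModel(tuple(segments), side, L) for side in ("cytoplasmic", "luminal")
    }

    from .motifs import has_dilysine

    if has_dilysine(ref):
        winner = next(
            s for s, m in candidates.items() if m.c_term_side == "cytoplasmic"
        )
        return TopologyModel(tuple(segments), winner, L, decided_by="dilysine")

    kr = {
        side: _kr_count(ref, m, "cytoplasmic") for side, m in candidates.items()
    }
    if kr["cytoplasmic"] >= kr["luminal"]:  # tie -> cytoplasmic N-terminus
        winner, rule = "cytoplasmic", "positive-inside"
        if kr["cytoplasmic"] == kr["luminal"]:
            rule = "tie-default"
    else:
        winner, rule = "luminal", "positive-inside"
    return TopologyModel(tuple(segments), winner, L, decided_by=rule)
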