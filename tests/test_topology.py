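"""topology: hydropathy profile, TM segmentation, refinement, orientation."""

import numpy as np
import pytest

from gtctopo import seqio, topology
from gtctopo.seqio import AlignedFamily, SequenceRecord
from gtctopo.topology import (
    KYTE_DOOLITTLE,
    SCALE_MIN,
    HydropathyProfile,
    TMDSegment,
    TopologyModel,
)


def _fam(*pairs, ref=None):
    fam = AlignedFamily(records=tuple(SequenceRecord(i, s) for i, s in pairs))
    if ref is not None:
        fam = seqio.set_reference(fam, ref)
    return fam


def _profile(smoothed, raw=None):
    """Hand-built profile (already smoothed) for direct segmentation tests."""
    smoothed = np.asarray(smoothed, dtype=float)
    raw = smoothed if raw is None else np.asarray(raw, dtype=float)
    L = len(smoothed)
    return HydropathyProfile(
        raw=raw, smoothed=smoothed, coverage=np.ones(L), window=19,
        low_coverage=np.zeros(L, dtype=bool),
    )


# ---------------------------------------------------------------------------
# hydropathy profile


def test_profile_all_ile():
    fam = _fam(("r", "IIIII"), ref="r")
    p = topology.hydropathy_profile(fam, window=5)
    assert np.allclose(p.raw, 4.5) and np.allclose(p.smoothed, 4.5)


def test_profile_all_ser():
    fam = _fam(("r", "SSSSS"), ref="r")
    p = topology.hydropathy_profile(fam, window=5)
    assert np.allclose(p.raw, -0.8)


def test_profile_mean_over_present_residues():
    fam = _fam(("r", "IIIII"), ("o", "I-LVF"), ref="r")
    p = topology.hydropathy_profile(fam, window=5)
    expect = [
        (4.5 + 4.5) / 2, 4.5, (4.5 + 3.8) / 2, (4.5 + 4.2) / 2, (4.5 + 2.8) / 2,
    ]
    assert np.allclose(p.raw, expect)
    assert p.coverage[1] == pytest.approx(0.5)


def test_profile_window_validation():
    fam = _fam(("r", "IIIII"), ref="r")
    with pytest.raises(ValueError):
        topology.hydropathy_profile(fam, window=4)
    with pytest.raises(ValueError):
        topology.hydropathy_profile(fam, window=3)


def test_profile_empty_column_imputed_and_flagged():
    fam = _fam(("r", "IXIII"), ("o", "I-III"), ref="r")
    p = topology.hydropathy_profile(fam, window=5)
    assert p.raw[1] == SCALE_MIN
    assert p.low_coverage[1]


def test_smoothing_shrinks_at_termini():
    fam = _fam(("r", "IWSIVGI"), ref="r")
    p = topology.hydropathy_profile(fam, window=5)
    # windows at positions 0 and L-1 shrink to width 1 (centred)
    assert p.smoothed[0] == p.raw[0]
    assert p.smoothed[-1] == p.raw[-1]
    # position 1 averages positions 0..2
    assert p.smoothed[1] == pytest.approx(p.raw[0:3].mean())


# ---------------------------------------------------------------------------
# segmentation


def test_segment_flat_hydrophilic_empty():
    assert topology.segment_tmds(_profile(np.full(60, -1.0))) == []


def test_segment_single_run():
    sm = np.full(60, -2.0)
    sm[10:31] = 3.0  # 21 positions, 1-based 11..31
    segs = topology.segment_tmds(_profile(sm), min_tm=15, max_tm=28)
    assert [(s.start, s.end) for s in segs] == [(11, 31)]


def test_segment_overlong_run_split_at_dip():
    sm = np.full(80, -2.0)
    sm[10:41] = 3.0          # 31 positions, 1-based 11..41
    sm[27] = 1.6             # interior dip at position 28 (>= threshold)
    # min_tm=10 margins leave candidates 21..31; the dip wins
    segs = topology.segment_tmds(_profile(sm), min_tm=10, max_tm=28)
    assert [(s.start, s.end) for s in segs] == [(11, 27), (29, 41)]
    # with min_tm=15 the margins leave position 26 as the only candidate
    segs = topology.segment_tmds(_profile(sm), min_tm=15, max_tm=28)
    assert [(s.start, s.end) for s in segs] == [(11, 25), (27, 41)]


def test_segment_short_runs_discarded():
    sm = np.full(60, -2.0)
    sm[5:15] = 3.0  # 10 < min_tm
    assert topology.segment_tmds(_profile(sm), min_tm=15) == []


def test_segment_min_ge_max_rejected():
    with pytest.raises(ValueError):
        topology.segment_tmds(_profile(np.zeros(10)), min_tm=20, max_tm=20)


def test_merge_gap_fuses_brief_dips():
    sm = np.full(60, -2.0)
    sm[10:20] = 3.0
    sm[22:32] = 3.0  # 2-position sub-threshold dip
    assert topology.segment_tmds(_profile(sm), min_tm=15) == []
    segs = topology.segment_tmds(_profile(sm), min_tm=15, merge_gap=3)
    assert [(s.start, s.end) for s in segs] == [(11, 32)]


def _oracle_segments(sm, threshold, min_tm, max_tm):
    """Independent exhaustive re-derivation of the segmentation contract."""
    runs, s = [], None
    for i, v in enumerate(sm):
        if v >= threshold and s is None:
            s = i + 1
        if v < threshold and s is not None:
            runs.append((s, i))
            s = None
    if s is not None:
        runs.append((s, len(sm)))

    def split(a, b):
        if b - a + 1 <= max_tm:
            return [(a, b)]
        lo, hi = a + min_tm, b - min_tm
        if lo > hi:
            return [(a, b)]
        cand = [(sm[p - 1], p) for p in range(lo, hi + 1)]
        m = min(cand)[1]  # leftmost minimum
        return split(a, m - 1) + split(m + 1, b)

    out = []
    for a, b in runs:
        if b - a + 1 >= min_tm:
            out.extend(split(a, b))
    return out


def test_segment_matches_exhaustive_oracle():
    rng = np.random.default_rng(42)
    for _ in range(30):
        L = int(rng.integers(80, 220))
        sm = rng.normal(0.0, 2.5, L)
        # add a few broad hydrophobic bumps so long runs occur
        for _ in range(int(rng.integers(1, 4))):
            c = int(rng.integers(10, L - 10))
            w = int(rng.integers(8, 25))
            sm[max(0, c - w):c + w] += 3.0
        segs = topology.segment_tmds(_profile(sm), threshold=1.5,
                                     min_tm=15, max_tm=28)
        assert [(s.start, s.end) for s in segs] == _oracle_segments(sm, 1.5, 15, 28)
        # every emitted segment respects the length bounds
        assert all(15 <= s.length <= 28 for s in segs)
        assert [s.index for s in segs] == list(range(1, len(segs) + 1))


def test_segment_translation_equivariance():
    sm = np.full(50, -2.0)
    sm[10:30] = 3.0
    base = topology.segment_tmds(_profile(sm))
    padded = topology.segment_tmds(_profile(np.concatenate([np.full(25, SCALE_MIN), sm])))
    assert [(s.start + 25, s.end + 25) for s in base] == \
        [(s.start, s.end) for s in padded]


# ---------------------------------------------------------------------------
# boundary refinement


def test_refine_snaps_to_raw_step():
    raw = np.full(70, -3.0)
    raw[20:40] = 3.5  # true helix 21..40
    prof = _profile(np.zeros(70), raw=raw)
    crude = [TMDSegment(1, 24, 37)]  # edges biased inward
    out = topology.refine_boundaries(crude, prof)
    assert [(s.start, s.end) for s in out] == [(21, 40)]


def test_refine_reverts_invalid_moves_and_never_overlaps():
    raw = np.full(90, -3.0)
    raw[10:30] = 3.5
    raw[35:55] = 3.5
    prof = _profile(np.zeros(90), raw=raw)
    crude = [TMDSegment(1, 12, 28), TMDSegment(2, 38, 53)]
    out = topology.refine_boundaries(crude, prof)
    assert len(out) == 2
    assert out[0].end < out[1].start
    assert all(15 <= s.length <= 28 for s in out)


# ---------------------------------------------------------------------------
# orientation


def _model_for(ref, segments, n_term="cytoplasmic"):
    fam = _fam(("r", ref), ref="r")
    return fam


def test_orient_positive_inside():
    # 1 helix; N-tail KKKK, C-tail SSSS -> cytoplasmic N-terminus
    ref = "KKKK" + "I" * 18 + "SSSS"
    fam = _fam(("r", ref), ref="r")
    segs = [TMDSegment(1, 5, 22)]
    m = topology.orient(segs, fam)
    assert m.n_term_side == "cytoplasmic"
    assert m.decided_by == "positive-inside"


def test_orient_dilysine_overrides_tally():
    # K/R tally favours a luminal C-terminus, but a dilysine signal forces
    # the C-terminus cytoplasmic
    ref = "SSSS" + "I" * 18 + "SSKKLA"
    fam = _fam(("r", ref), ref="r")
    segs = [TMDSegment(1, 5, 22)]
    m = topology.orient(segs, fam)
    assert m.decided_by == "dilysine"
    assert m.c_term_side == "cytoplasmic"


def test_orient_tie_defaults_cytoplasmic_n_terminus():
    ref = "KSSS" + "I" * 18 + "KSSS"
    fam = _fam(("r", ref), ref="r")
    m = topology.orient([TMDSegment(1, 5, 22)], fam)
    assert m.n_term_side == "cytoplasmic"
    assert m.decided_by == "tie-default"


def test_orient_empty_segments_rejected():
    fam = _fam(("r", "ACD"), ref="r")
    with pytest.raises(RuntimeError):
        topology.orient([], fam)


# ---------------------------------------------------------------------------
# model structure


def test_loop_sides_alternate():
    segs = tuple(TMDSegment(i + 1, 1 + 30 * i, 20 + 30 * i) for i in range(4))
    m = TopologyModel(segs, "cytoplasmic", 140)
    sides = [lp.side for lp in m.loops()]
    assert all(a != b for a, b in zip(sides, sides[1:]))
    assert m.c_term_side == "cytoplasmic"  # even helix count


def test_side_masks_cover_loops_only():
    segs = (TMDSegment(1, 11, 28), TMDSegment(2, 40, 58))
    m = TopologyModel(segs, "cytoplasmic", 70)
    masks = m.side_mask()
    both = masks["cytoplasmic"] | masks["luminal"]
    in_tm = np.zeros(70, dtype=bool)
    for s in segs:
        in_tm[s.start - 1:s.end] = True
    assert not (both & in_tm).any()
    assert (both | in_tm).all()


def test_labelled_loops_el_cl_numbering():
    segs = tuple(TMDSegment(i + 1, 1 + 30 * i, 20 + 30 * i) for i in range(3))
    m = TopologyModel(segs, "cytoplasmic", 110)
    names = [n for n, _ in m.labelled_loops()]
    assert names == ["N-term", "EL1", "CL1", "C-term"]


def test_overlapping_segments_rejected():
    with pytest.raises(ValueError):
        TopologyModel((TMDSegment(1, 1, 20), TMDSegment(2, 15, 40)), "cytoplasmic", 60)
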