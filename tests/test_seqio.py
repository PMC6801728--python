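"""seqio: parsing, reference coordinates and diverse-subset selection."""

import itertools

import numpy as np
import pytest

from gtctopo import seqio
from gtctopo.seqio import (
    GAP_IN_REFERENCE,
    AlignedFamily,
    MalformedInputError,
    SequenceRecord,
)


def _fam(*pairs, ref=None):
    fam = AlignedFamily(records=tuple(SequenceRecord(i, s) for i, s in pairs))
    if ref is not None:
        fam = seqio.set_reference(fam, ref)
    return fam


# ---------------------------------------------------------------------------
# reading / writing


def test_read_fasta_alignment(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">a\nACDEFGHIKL\n>b\nACDEFGHIKV\n>c\nACDEFGHIK-\n")
    fam = seqio.read_alignment(p, "fasta")
    assert fam.n == 3 and fam.length == 10
    assert fam.ids == ("a", "b", "c")


def test_ragged_fasta_names_offending_record(tmp_path):
    p = tmp_path / "ragged.fasta"
    p.write_text(">ok\nACDEF\n>short\nACDE\n")
    with pytest.raises(MalformedInputError, match="short"):
        seqio.read_alignment(p, "fasta")


def test_unknown_format_rejected(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">a\nACD\n")
    with pytest.raises(ValueError, match="format"):
        seqio.read_alignment(p, "phylip")


@pytest.mark.parametrize("fmt", ["fasta", "stockholm", "clustal"])
def test_round_trip_involution(tmp_path, fmt):
    fam = _fam(("alpha", "ACD-EF"), ("beta", "ACDWEF"), ("gamma", "AC-WEF"))
    p = tmp_path / f"out.{fmt}"
    seqio.write_alignment(fam, p, fmt)
    back = seqio.read_alignment(p, fmt)
    assert back.ids == fam.ids
    assert [r.residues for r in back.records] == [r.residues for r in fam.records]


def test_invalid_residue_rejected():
    with pytest.raises(ValueError, match="invalid residue"):
        SequenceRecord("bad", "ACDZ")


def test_empty_record_rejected():
    with pytest.raises(ValueError, match="empty"):
        SequenceRecord("bad", "")


# ---------------------------------------------------------------------------
# reference coordinates


def test_column_map_definition():
    fam = _fam(("r", "A-CD"), ("o", "AXCD"), ref="r")
    assert fam.column_map == (1, GAP_IN_REFERENCE, 2, 3)


def test_column_map_gapless_is_identity():
    fam = _fam(("r", "ACDEF"), ("o", "ACDEW"), ref="r")
    assert fam.column_map == (1, 2, 3, 4, 5)


def test_gap_plus_mapped_counts_conserve_length():
    fam = _fam(("r", "A--CD-EF"), ("o", "AWWCDWEF"), ref="r")
    gaps = sum(1 for v in fam.column_map if v == GAP_IN_REFERENCE)
    mapped = sum(1 for v in fam.column_map if v != GAP_IN_REFERENCE)
    assert gaps + mapped == fam.length


def test_missing_reference_raises():
    fam = _fam(("r", "ACD"))
    with pytest.raises(KeyError):
        seqio.set_reference(fam, "nope")


def test_degap_to_reference_example():
    fam = _fam(("r", "A-CD"), ("o", "AXCD"), ref="r")
    out = seqio.degap_to_reference(fam)
    assert out.length == 3
    assert out.reference.residues == "ACD"
    assert out.records[1].residues == "ACD"
    assert out.column_map == (1, 2, 3)


def test_degap_gapless_identity():
    fam = _fam(("r", "ACDEF"), ("o", "AC-EW"), ref="r")
    out = seqio.degap_to_reference(fam)
    assert [r.residues for r in out.records] == [r.residues for r in fam.records]


def test_degap_property_random_fixtures():
    rng = np.random.default_rng(17)
    letters = np.array(list(seqio.AMINO_ACIDS + "-"))
    for _ in range(20):
        L = int(rng.integers(5, 30))
        rows = ["".join(rng.choice(letters, L)) for _ in range(4)]
        # keep the reference non-empty after degapping
        rows[0] = rows[0][:-1] + "A"
        fam = seqio.set_reference(
            AlignedFamily(tuple(SequenceRecord(f"s{i}", r) for i, r in enumerate(rows))),
            "s0",
        )
        out = seqio.degap_to_reference(fam)
        assert out.length == len(fam.reference.ungapped())
        keep = [c for c, v in enumerate(fam.column_map) if v != GAP_IN_REFERENCE]
        for orig, new in zip(fam.records, out.records):
            assert new.residues == "".join(orig.residues[c] for c in keep)


def test_degap_requires_reference():
    fam = _fam(("r", "ACD"))
    with pytest.raises(RuntimeError):
        seqio.degap_to_reference(fam)


# ---------------------------------------------------------------------------
# diversity selection


def test_pairwise_distance_basics():
    recs = [SequenceRecord("a", "AAAA"), SequenceRecord("b", "AAAT"),
            SequenceRecord("c", "----")]
    dm = seqio.pairwise_distances(recs)
    assert dm.get("a", "a") == 0.0
    assert dm.get("a", "b") == pytest.approx(0.25)
    assert dm.get("a", "b") == dm.get("b", "a")
    assert dm.get("a", "c") == 1.0  # no comparable positions


def test_select_diverse_k_equals_n():
    recs = [SequenceRecord(i, s) for i, s in
            [("a", "AAAA"), ("b", "AATT"), ("c", "TTTT")]]
    assert sorted(seqio.select_diverse(recs, 3)) == ["a", "b", "c"]


def test_select_diverse_line_picks_endpoints():
    # identity distances form a line: d(s1,s4) is maximal
    recs = [SequenceRecord(i, s) for i, s in
            [("s1", "AAAAAAAA"), ("s2", "AAAAAATT"),
             ("s3", "AAAATTTT"), ("s4", "AATTTTTT")]]
    assert set(seqio.select_diverse(recs, 2)) == {"s1", "s4"}


def test_select_diverse_k_exceeds_n():
    recs = [SequenceRecord("a", "AAAA")]
    with pytest.raises(ValueError):
        seqio.select_diverse(recs, 2)


def test_select_diverse_order_invariance():
    rng = np.random.default_rng(5)
    letters = np.array(list("ACDE"))
    recs = [SequenceRecord(f"s{i}", "".join(rng.choice(letters, 12)))
            for i in range(8)]
    base = seqio.select_diverse(recs, 3)
    shuffled = list(recs)
    rng.shuffle(shuffled)
    assert sorted(seqio.select_diverse(shuffled, 3)) == sorted(base)


def test_select_diverse_vs_exhaustive_oracle():
    """Greedy maximin is a 2-approximation of the optimal C(8,3) subset."""
    rng = np.random.default_rng(23)
    letters = np.array(list("ACDEFG"))
    for rep in range(5):
        recs = [SequenceRecord(f"s{i}", "".join(rng.choice(letters, 15)))
                for i in range(8)]
        dm = seqio.pairwise_distances(recs)
        idx = {s: i for i, s in enumerate(dm.ids)}

        def min_pairwise(ids):
            return min(dm.d[idx[a], idx[b]] for a, b in itertools.combinations(ids, 2))

        best = max(min_pairwise(c) for c in itertools.combinations(dm.ids, 3))
        greedy = min_pairwise(seqio.select_diverse(recs, 3))
        assert greedy >= best / 2 - 1e-12
        assert greedy <= best + 1e-12


def test_select_diverse_include_and_seed():
    recs = [SequenceRecord(i, s) for i, s in
            [("a", "AAAA"), ("b", "AATT"), ("c", "TTTT"), ("d", "TTAA")]]
    out = seqio.select_diverse(recs, 2, include=["b"])
    assert "b" in out and len(out) == 2
    out = seqio.select_diverse(recs, 2, seed_id="c")
    assert out[0] == "c"
    with pytest.raises(KeyError):
        seqio.select_diverse(recs, 2, seed_id="zz")
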