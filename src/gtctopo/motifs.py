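"""Degenerate protein motif grammar, scanning and loop assignment.

The catalytic residues of GT-C glycosyltransferases cluster into a handful
of short degenerate patterns in luminal loops: an acidic D/E pair shortly
after the first helix (DxD-like, where D can be E and the spacer may be
absent), an arginine-anchored acidic motif in luminal loop 2, a conserved
basic position in loop 3, and an Rx(4-14)P motif in the C-terminal helix
cluster.  A C-terminal dilysine ER-retrieval signal marks the families
whose C-terminus faces the cytoplasm.

Pattern grammar (PROSITE-like):

* a residue letter matches itself, ``x`` matches any residue;
* ``[DE]`` matches a residue class;
* ``{m}`` / ``{m,n}`` repeat the preceding element m (to n) times;
* ``?`` makes the preceding element optional;
* a trailing ``$`` anchors the match to the C-terminus;
* ``|`` separates top-level alternatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from .seqio import AMINO_ACIDS
from .topology import TopologyModel

ALL = frozenset(AMINO_ACIDS)


class PatternSyntaxError(ValueError):
    """Raised with a position pointer when a pattern string does not parse."""

    def __init__(self, pattern: str, pos: int, msg: str):
        super().__init__(f"{msg} at position {pos} in {pattern!r}")
        self.pos = pos


@dataclass(frozen=True)
class _Element:
    allowed: frozenset[str]
    min_count: int = 1
    max_count: int = 1


@dataclass(frozen=True)
class _Alternative:
    elements: tuple[_Element, ...]
    anchored: bool = False  # must end at the C-terminus

    @property
    def min_len(self) -> int:
        return sum(e.min_count for e in self.elements)

    @property
    def max_len(self) -> int:
        return sum(e.max_count for e in self.elements)


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate pattern with its expected membrane side."""

    name: str
    pattern: str  # normalized grammar string
    expected_side: str = "either"  # luminal | cytoplasmic | either
    alternatives: tuple[_Alternative, ...] = ()
    conserved_position: bool = False  # realized via conservation calls, not scanning

    @property
    def min_len(self) -> int:
        return min(a.min_len for a in self.alternatives)

    @property
    def max_len(self) -> int:
        return max(a.max_len for a in self.alternatives)


@dataclass
class MotifHit:
    """A pattern match in 1-based inclusive reference coordinates."""

    name: str
    start: int
    end: int
    matched: str
    loop_label: Optional[str] = None
    side: Optional[str] = None


# ---------------------------------------------------------------------------
# compilation


def _parse_alternative(alt: str, full: str, offset: int) -> _Alternative:
    elements: list[_Element] = []
    anchored = False
    i = 0
    n = len(alt)
    while i < n:
        ch = alt[i]
        pos = offset + i
        if anchored:
            raise PatternSyntaxError(full, pos, "'$' must terminate the pattern")
        if ch == "[":
            j = alt.find("]", i)
            if j < 0:
                raise PatternSyntaxError(full, pos, "unterminated '['")
            members = alt[i + 1 : j]
            if not members or any(c not in AMINO_ACIDS for c in members):
                raise PatternSyntaxError(full, pos, "invalid residue class")
            allowed = frozenset(members)
            i = j + 1
        elif ch == "x":
            allowed = ALL
            i += 1
        elif ch in AMINO_ACIDS:
            allowed = frozenset(ch)
            i += 1
        elif ch == "$":
            anchored = True
            i += 1
            continue
        else:
            raise PatternSyntaxError(full, pos, f"unexpected character {ch!r}")
        # optional repeat / optional suffix
        mn, mx = 1, 1
        if i < n and alt[i] == "{":
            j = alt.find("}", i)
            if j < 0:
                raise PatternSyntaxError(full, offset + i, "unterminated '{'")
            body = alt[i + 1 : j]
            try:
                if "," in body:
                    a, b = body.split(",")
                    mn, mx = int(a), int(b)
                else:
                    mn = mx = int(body)
            except ValueError:
                raise PatternSyntaxError(full, offset + i, "malformed repeat") from None
            if mn < 0 or mn > mx:
                raise PatternSyntaxError(
                    full, offset + i, f"repeat bounds {mn} > {mx}"
                )
            i = j + 1
        elif i < n and alt[i] == "?":
            mn, mx = 0, 1
            i += 1
        elements.append(_Element(allowed, mn, mx))
    if not elements:
        raise PatternSyntaxError(full, offset, "empty alternative")
    return _Alternative(tuple(elements), anchored)


def _normalize(alt: _Alternative) -> str:
    parts = []
    for e in alt.elements:
        if e.allowed == ALL:
            token = "x"
        elif len(e.allowed) == 1:
            token = next(iter(e.allowed))
        else:
            token = "[" + "".join(sorted(e.allowed)) + "]"
        if (e.min_count, e.max_count) == (1, 1):
            pass
        elif (e.min_count, e.max_count) == (0, 1):
            token += "?"
        elif e.min_count == e.max_count:
            token += "{%d}" % e.min_count
        else:
            token += "{%d,%d}" % (e.min_count, e.max_count)
        parts.append(token)
    return "".join(parts) + ("$" if alt.anchored else "")


def compile(pattern: str, name: str = "", expected_side: str = "either") -> MotifPattern:
    """Compile a grammar string into a scannable :class:`MotifPattern`."""
    alternatives = []
    offset = 0
    for chunk in pattern.split("|"):
        stripped = chunk.strip()
        if not stripped:
            raise PatternSyntaxError(pattern, offset, "empty alternative")
        alternatives.append(
            _parse_alternative(stripped, pattern, offset + chunk.index(stripped[0]))
        )
        offset += len(chunk) + 1
    normalized = "|".join(_normalize(a) for a in alternatives)
    return MotifPattern(
        name=name or normalized,
        pattern=normalized,
        expected_side=expected_side,
        alternatives=tuple(alternatives),
    )


# ---------------------------------------------------------------------------
# scanning


def _matches_from(seq: str, start0: int, elements: tuple[_Element, ...]) -> set[int]:
    """End offsets (exclusive, 0-based) of all matches starting at start0."""
    ends = {start0}
    for e in elements:
        nxt: set[int] = set()
        for pos in ends:
            # consume between min_count and max_count residues from ``pos``
            ok = 0
            while ok < e.max_count and pos + ok < len(seq) and seq[pos + ok] in e.allowed:
                ok += 1
            for k in range(e.min_count, ok + 1):
                nxt.add(pos + k)
        ends = nxt
        if not ends:
            break
    return ends


def scan(
    sequence: str, pattern: MotifPattern, overlapping: bool = True
) -> list[MotifHit]:
    """All matches of ``pattern`` in ``sequence`` (1-based coordinates).

    With ``overlapping`` every admissible (start, width) combination is
    reported, leftmost-first then shortest-first; otherwise only the
    leftmost-shortest match is kept and scanning resumes after its end.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    n = len(seq)
    spans: set[tuple[int, int]] = set()
    for alt in pattern.alternatives:
        for s in range(n):
            for e in _matches_from(seq, s, alt.elements):
                if e == s:
                    continue  # zero-width matches are not reported
                if alt.anchored and e != n:
                    continue
                spans.add((s, e))
    for s, e in sorted(spans):
        hits.append(MotifHit(pattern.name, s + 1, e, seq[s:e]))
    if overlapping:
        return hits
    kept: list[MotifHit] = []
    cursor = 0  # 1-based position after the last kept match
    for h in hits:
        if h.start > cursor:
            kept.append(h)
            cursor = h.end
    return kept


def assign_loops(hits: Sequence[MotifHit], model: TopologyModel) -> list[MotifHit]:
    """Attach loop labels and membrane sides to hits.

    A hit overlapping any TM helix is labelled ``TMD-embedded`` (side left
    unset); otherwise its loop is the interval containing its start.
    Coordinates are never modified.
    """
    loops = model.labelled_loops()
    out: list[MotifHit] = []
    for h in hits:
        if h.end > model.length or h.start < 1:
            raise IndexError(
                f"hit {h.name} at {h.start}-{h.end} beyond model length {model.length}"
            )
        in_tmd = any(
            h.start <= seg.end and h.end >= seg.start for seg in model.segments
        )
        if in_tmd:
            out.append(replace_hit(h, "TMD-embedded", None))
            continue
        for name, lp in loops:
            if lp.length and lp.start <= h.start <= lp.end:
                out.append(replace_hit(h, name, lp.side))
                break
        else:  # pragma: no cover - unreachable for a covering model
            raise IndexError(f"hit {h.name} at {h.start} not inside any loop")
    return out


def replace_hit(h: MotifHit, loop_label: Optional[str], side: Optional[str]) -> MotifHit:
    return MotifHit(h.name, h.start, h.end, h.matched, loop_label, side)


def has_dilysine(sequence: str) -> bool:
    """C-terminal dilysine ER-retrieval signal: K at -3 and -4 (KKxx) or
    -3 and -5 (KxKxx)."""
    s = sequence.upper()
    kkxx = len(s) >= 4 and s[-4] == "K" and s[-3] == "K"
    kxkxx = len(s) >= 5 and s[-5] == "K" and s[-3] == "K"
    return kkxx or kxkxx


# ---------------------------------------------------------------------------
# curated library and family registry

DILYSINE_PATTERN = "KKxx$|KxKxx$"


def library() -> dict[str, MotifPattern]:
    """The curated GT-C motif library, keyed by motif name.

    ``EL3_basic`` is a conserved-position class (a single residue); it is
    evaluated through conservation calls restricted to the loop rather than
    by string scanning, and is marked accordingly.
    """
    pats = {
        "EL1_acidic": compile("[DE]x?[DE]", "EL1_acidic", "luminal"),
        "EL2_Rx6": compile("Rx{6}[DL][NR]E", "EL2_Rx6", "luminal"),
        "EL2_Rx4D": compile("Rx{4}D", "EL2_Rx4D", "luminal"),
        "EL3_basic": replace(
            compile("[KNQR]", "EL3_basic", "luminal"), conserved_position=True
        ),
        "EL_RxP": compile("Rx{4,14}P", "EL_RxP", "luminal"),
        "dilysine": compile(DILYSINE_PATTERN, "dilysine", "cytoplasmic"),
    }
    return pats


@dataclass(frozen=True)
class FamilyEntry:
    """Expected architecture of one GT-C family."""

    name: str
    n_tmds: int
    organization: str
    dilysine: bool = False
    absent_motifs: frozenset[str] = frozenset()
    expected_motifs: tuple[str, ...] = (
        "EL1_acidic",
        "EL2_Rx6",
        "EL3_basic",
        "EL_RxP",
    )


def _entry(name, n, org, **kw):
    return FamilyEntry(name=name, n_tmds=n, organization=org, **kw)


FAMILY_REGISTRY: dict[str, FamilyEntry] = {
    e.name: e
    for e in [
        _entry("POMT", 11, "1-6-4",
               expected_motifs=("EL1_acidic", "EL2_Rx4D", "EL3_basic", "EL_RxP")),
        _entry("TMTC", 11, "1-6-4",
               expected_motifs=("EL1_acidic", "EL2_Rx4D", "EL3_basic", "EL_RxP")),
        _entry("ALG9", 11, "1-6-4",
               absent_motifs=frozenset({"EL2_Rx6", "EL2_Rx4D", "EL3_basic"}),
               expected_motifs=("EL1_acidic", "EL_RxP")),
        _entry("ALG12", 11, "1-6-4"),
        _entry("PIGB", 11, "1-6-4"),
        _entry("PIGZ", 11, "1-6-4"),
        _entry("PIGV", 11, "1-6-4"),
        _entry("STT3", 13, "1-8-4"),
        _entry("DPY19", 13, "1-8-4"),
        _entry("ALG10", 13, "1-8-4"),
        _entry("ALG3", 12, "1-6-5", dilysine=True),
        _entry("PIGM", 12, "1-6-5", dilysine=True),
        _entry("ALG6", 14, "1-6-7", dilysine=True),
        _entry("ALG8", 14, "1-6-7", dilysine=True),
    ]
}


def registry(family: str) -> FamilyEntry:
    """Look up a GT-C family's expected helix count and organization."""
    try:
        return FAMILY_REGISTRY[family.upper()]
    except KeyError:
        raise KeyError(
            f"unknown family {family!r}; known: {sorted(FAMILY_REGISTRY)}"
        ) from None


def save_library(patterns: dict[str, MotifPattern], path: str | Path) -> None:
    """Write the library as an editable JSON config."""
    payload = [
        {
            "name": p.name,
            "pattern": p.pattern,
            "expected_side": p.expected_side,
            "conserved_position": p.conserved_position,
        }
        for p in patterns.values()
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_library(path: str | Path) -> dict[str, MotifPattern]:
    """Read a JSON motif config written by :func:`save_library`."""
    out = {}
    for item in json.loads(Path(path).read_text()):
        p = compile(item["pattern"], item["name"], item.get("expected_side", "either"))
        if item.get("conserved_position"):
            p = replace(p, conserved_position=True)
        out[p.name] = p
    return out
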