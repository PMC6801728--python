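"""Synthetic multi-pass membrane-protein families with known ground truth.

The generator emulates the statistical structure that the analysis relies
on in real GT-C families:

* a fixed helix architecture (11/12/13/14 TMDs) with strongly hydrophobic
  membrane segments (Ile/Leu/Val/Phe/Ala/Met alphabet, Kyte-Doolittle mean
  ~3.5) and hydrophilic loops;
* short cytoplasmic loops enriched in Lys/Arg (positive-inside rule) and
  larger luminal loops mildly depleted of Lys/Arg;
* hydrophilic flanking residues at both ends of every loop, emulating the
  charged/polar helix-capping belts of real membrane proteins and keeping
  helix boundaries identifiable from sequence;
* near-invariant planted motif instances and conserved areas in designated
  loops (the catalytic luminal motifs), with everything else diverged by
  per-position substitution noise drawn from region-appropriate
  distributions;
* an optional C-terminal dilysine ER-retrieval signal.

Families are gapless by construction, so alignment columns equal template
positions and ground-truth coordinates are trivial.  The first record is
the unmutated template and serves as the reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seqio import AMINO_ACIDS, AlignedFamily, SequenceRecord, set_reference
from .topology import KYTE_DOOLITTLE

HYDROPHOBIC = "ILVFAM"
#: loop-flank alphabet: polar/charged/aromatic residues found at helix caps
FLANK_ALPHABET = "GTSWYPHEQDNKR"

_TM_WEIGHTS = {"I": 0.20, "L": 0.25, "V": 0.20, "F": 0.15, "A": 0.10, "M": 0.10}

#: loop background: polar/charged/aromatic residues at full weight, the
#: hydrophobic/TM-like residues strongly downweighted.  Loops of polytopic
#: membrane proteins are polar-enriched; a flat composition would sprinkle
#: Ile/Leu/Val clusters into loops, and a chance cluster abutting a helix
#: makes that boundary unrecoverable from hydropathy for any method.
_LOOP_WEIGHTS = {a: 1.0 for a in FLANK_ALPHABET}
_LOOP_WEIGHTS.update({a: 0.15 for a in "AILMFVC"})
#: residues counted as hydrophobic for the loop cluster-avoidance rule
_LOOP_HYDROPHOBIC = set("AILMFVC")


class SpecError(ValueError):
    """Raised when a family specification is internally inconsistent."""


@dataclass(frozen=True)
class PlantedMotif:
    """A concrete motif instance planted into one loop.

    ``after_helix`` identifies the loop: 0 is the N-terminal tail, ``i`` the
    loop following helix ``i``, ``n_tmds`` the C-terminal tail.
    """

    name: str
    instance: str
    after_helix: int
    side: str  # luminal | cytoplasmic


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic family."""

    n_tmds: int = 13
    tm_len_range: tuple[int, int] = (18, 25)
    short_loop_range: tuple[int, int] = (5, 15)
    large_loop_range: tuple[int, int] = (40, 90)
    large_loop_after: tuple[int, ...] = (1, 9)
    planted_motifs: tuple[PlantedMotif, ...] = ()
    n_seqs: int = 25
    sub_rate: float = 0.3
    motif_sub_rate: float = 0.02
    positive_inside_bias: float = 0.35
    luminal_kr_frequency: float = 0.03
    flank_len: int = 4
    dilysine: bool = False
    grow_loops_for_motifs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tmds < 3:
            raise SpecError("n_tmds must be >= 3")
        for r in (self.sub_rate, self.motif_sub_rate):
            if not 0 <= r <= 1:
                raise SpecError("substitution rates must lie in [0, 1]")
        if not 0 <= self.positive_inside_bias <= 0.9:
            raise SpecError("positive_inside_bias out of range")
        for pm in self.planted_motifs:
            if not 0 <= pm.after_helix <= self.n_tmds:
                raise SpecError(
                    f"motif {pm.name!r}: loop after helix {pm.after_helix} "
                    f"does not exist for {self.n_tmds} TMDs"
                )
        for h in self.large_loop_after:
            if not 1 <= h <= self.n_tmds - 1:
                raise SpecError(f"large loop after helix {h} out of range")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth accompanying a generated family."""

    template: str
    tmd_bounds: tuple[tuple[int, int], ...]  # 1-based inclusive
    loop_sides: tuple[str, ...]              # N-tail, inter-loops, C-tail
    motif_positions: tuple[tuple[str, int, int], ...]  # (name, start, end)
    n_term_side: str = "cytoplasmic"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "template": self.template,
            "tmd_bounds": list(map(list, self.tmd_bounds)),
            "loop_sides": list(self.loop_sides),
            "motif_positions": [list(m) for m in self.motif_positions],
            "n_term_side": self.n_term_side,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# architecture presets

#: canonical helix count per architecture (extras are C-terminal additions)
_CANONICAL = {11: 11, 12: 11, 13: 13, 14: 11}

#: default planted instances (catalytic luminal motifs + conserved areas)
_EL1_INSTANCE = "ESE"            # matches [DE]x?[DE]
_EL2_INSTANCE = "RAGTSVQLRE"     # matches Rx{6}[DL][NR]E
_EL3_INSTANCE = "R"              # conserved basic position
_RXP_INSTANCE = "RAGSTP"         # matches Rx{4,14}P
# Conserved areas: large near-invariant blocks occupying a substantial part
# of their luminal loops, as in the real families (a 77-residue conserved
# EL1, the large conserved area between the two C-proximal helix clusters,
# and the conserved luminal C-terminal domain).  Lys/Arg-free so they do
# not perturb the positive-inside signal.
_EL1_AREA = "DWSGYSENQTDYPHESGTWDQNSE"
_EL3_AREA = "DWNDYGSQTE"
_EL4_AREA = "ESNQWYDTGHSPYE"
_PRECLUSTER_AREA = "DTWNEAGYSDQPHESNYTDGWQESPTHNDYSGQEWT"
_CTERM_AREA = "ENLYSDGWQTPAHSEDNTYWGQSPEHDNSGYTEQWD"


def default_spec(n_tmds: int = 13, seed: int = 0, **overrides) -> FamilySpec:
    """A family specification following the common GT-C architecture.

    Large luminal loops sit after helix 1 and after helix ``canonical - 4``
    (canonical = 11 or 13); 12- and 14-helix architectures append one or
    three extra C-terminal helices and carry a cytoplasmic dilysine signal.
    """
    if n_tmds not in _CANONICAL:
        raise SpecError(f"no preset architecture for {n_tmds} TMDs")
    canonical = _CANONICAL[n_tmds]
    dilysine = n_tmds != canonical
    precluster = canonical - 4  # loop before the last-four helix cluster
    motifs = [
        PlantedMotif("EL1_acidic", _EL1_INSTANCE, 1, "luminal"),
        PlantedMotif("area_el1", _EL1_AREA, 1, "luminal"),
        PlantedMotif("EL2_Rx6", _EL2_INSTANCE, 3, "luminal"),
        PlantedMotif("EL3_basic", _EL3_INSTANCE, 5, "luminal"),
        PlantedMotif("area_el3", _EL3_AREA, 5, "luminal"),
        PlantedMotif("area_precluster", _PRECLUSTER_AREA, precluster, "luminal"),
        PlantedMotif("EL_RxP", _RXP_INSTANCE, canonical - 2, "luminal"),
    ]
    if canonical == 13:  # loop after helix 7 would otherwise be bare
        motifs.append(PlantedMotif("area_el4", _EL4_AREA, 7, "luminal"))
    if not dilysine:  # luminal C-terminal tail carries a conserved area
        motifs.append(PlantedMotif("area_cterm", _CTERM_AREA, n_tmds, "luminal"))
    kw = dict(
        n_tmds=n_tmds,
        large_loop_after=(1, precluster),
        planted_motifs=tuple(motifs),
        dilysine=dilysine,
        seed=seed,
    )
    kw.update(overrides)
    return FamilySpec(**kw)


# ---------------------------------------------------------------------------
# generation helpers


def _loop_side(after_helix: int, n_term_side: str = "cytoplasmic") -> str:
    if after_helix % 2 == 0:
        return n_term_side
    return "luminal" if n_term_side == "cytoplasmic" else "cytoplasmic"


def _distribution(letters: str, weights: Optional[dict[str, float]] = None,
                  boost: Optional[dict[str, float]] = None) -> tuple[np.ndarray, str]:
    """Probability vector over ``letters`` with additive boosts, renormalized.

    Weights are normalized to probabilities *before* boosts apply, so boost
    magnitudes are always in probability units.
    """
    p = np.array(
        [weights.get(a, 0.0) if weights else 1.0 for a in letters]
    )
    p = p / p.sum()
    if boost:
        for a, b in boost.items():
            if a in letters:
                p[letters.index(a)] += b
    p = np.clip(p, 0.0, None)
    return p / p.sum(), letters


def _region_distributions(spec: FamilySpec) -> dict[str, tuple[np.ndarray, str]]:
    half_bias = spec.positive_inside_bias / 2.0
    lum_kr = spec.luminal_kr_frequency
    # per-residue K (and R) background frequency under each base composition
    loop_kr = _LOOP_WEIGHTS["K"] / sum(_LOOP_WEIGHTS.values())
    flank_kr = 1.0 / len(FLANK_ALPHABET)
    dists = {
        "tm": _distribution(HYDROPHOBIC, weights=_TM_WEIGHTS),
        "cyto": _distribution(
            AMINO_ACIDS, weights=_LOOP_WEIGHTS,
            boost={"K": half_bias, "R": half_bias},
        ),
        "luminal": _distribution(
            AMINO_ACIDS, weights=_LOOP_WEIGHTS,
            boost={"K": lum_kr / 2 - loop_kr, "R": lum_kr / 2 - loop_kr},
        ),
        "cyto_flank": _distribution(
            FLANK_ALPHABET, boost={"K": half_bias, "R": half_bias}
        ),
        "luminal_flank": _distribution(
            FLANK_ALPHABET,
            boost={"K": lum_kr / 2 - flank_kr, "R": lum_kr / 2 - flank_kr},
        ),
    }
    return dists


def _resolve_loop(pm: PlantedMotif, spec: FamilySpec) -> int:
    """Loop index whose membrane side matches the motif's declared side."""
    if _loop_side(pm.after_helix) == pm.side:
        return pm.after_helix
    for h in (pm.after_helix + 1, pm.after_helix - 1):
        if 0 <= h <= spec.n_tmds and _loop_side(h) == pm.side:
            return h
    raise SpecError(f"motif {pm.name!r}: no loop with side {pm.side!r} nearby")


def generate(spec: FamilySpec) -> tuple[AlignedFamily, SyntheticTruth]:
    """Draw one family and its ground truth, deterministically from the seed."""
    rng = np.random.default_rng(spec.seed)
    dists = _region_distributions(spec)
    n = spec.n_tmds

    # --- layout: loop index 0..n, helix i between loop i-1 and loop i
    planted_by_loop: dict[int, list[PlantedMotif]] = {}
    for pm in spec.planted_motifs:
        planted_by_loop.setdefault(_resolve_loop(pm, spec), []).append(pm)

    def draw_len(lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi + 1))

    loop_lengths: list[int] = []
    for h in range(n + 1):
        if h in spec.large_loop_after:
            lo, hi = spec.large_loop_range
        elif h == n and _loop_side(n) == "luminal":
            lo, hi = spec.large_loop_range  # large luminal C-terminal domain
        else:
            lo, hi = spec.short_loop_range
        length = draw_len(lo, hi)
        required = 2 + sum(len(pm.instance) + 2 for pm in planted_by_loop.get(h, ()))
        if h == n and spec.dilysine:
            required += 4
        if required > length:
            if not spec.grow_loops_for_motifs:
                raise SpecError(
                    f"loop after helix {h} too short ({length}) for planted "
                    f"motifs needing {required} residues"
                )
            length = required
        loop_lengths.append(length)
    tm_lengths = [draw_len(*spec.tm_len_range) for _ in range(n)]

    # --- template assembly with region bookkeeping
    regions: list[str] = []  # per-position region key
    template: list[str] = []
    tmd_bounds: list[tuple[int, int]] = []
    loop_spans: list[tuple[int, int]] = []  # 1-based inclusive, may be empty

    def emit_loop(h: int, length: int) -> None:
        side = _loop_side(h)
        start = len(template) + 1
        flank = spec.flank_len
        prev = ""
        for i in range(length):
            near_n = i < flank and h > 0          # abuts the previous helix
            near_c = i >= length - flank and h < n  # abuts the next helix
            key = f"{'cyto' if side == 'cytoplasmic' else 'luminal'}"
            if near_n or near_c:
                key += "_flank"
            p, letters = dists[key]
            aa = letters[int(rng.choice(len(letters), p=p))]
            # no two consecutive hydrophobic residues within a loop: a
            # hydrophobic cluster would partition into the bilayer, and it
            # would make the adjacent helix boundary ill-defined
            while prev in _LOOP_HYDROPHOBIC and aa in _LOOP_HYDROPHOBIC:
                aa = letters[int(rng.choice(len(letters), p=p))]
            template.append(aa)
            prev = aa
            regions.append(key)
        loop_spans.append((start, len(template)))

    for h in range(n + 1):
        if h > 0:
            s = len(template) + 1
            p, letters = dists["tm"]
            for _ in range(tm_lengths[h - 1]):
                template.append(letters[int(rng.choice(len(letters), p=p))])
                regions.append("tm")
            tmd_bounds.append((s, len(template)))
        emit_loop(h, loop_lengths[h])

    # --- overwrite planted motifs (and the dilysine signal)
    motif_positions: list[tuple[str, int, int]] = []
    is_motif = np.zeros(len(template), dtype=bool)
    for h, pms in sorted(planted_by_loop.items()):
        start, end = loop_spans[h]
        offset = start + 2  # leave room for the flank
        for pm in pms:
            a, b = offset, offset + len(pm.instance) - 1
            template[a - 1 : b] = list(pm.instance)
            is_motif[a - 1 : b] = True
            motif_positions.append((pm.name, a, b))
            offset = b + 3
    if spec.dilysine:
        # C-terminal KKxx ER-retrieval signal on a cytoplasmic tail
        L = len(template)
        template[L - 4 : L - 2] = ["K", "K"]
        is_motif[L - 4 : L - 2] = True
        motif_positions.append(("dilysine", L - 3, L))

    template_str = "".join(template)

    # --- sequences: reference = template, others carry substitutions
    records = [SequenceRecord(id="ref", residues=template_str)]
    L = len(template_str)
    rates = np.where(is_motif, spec.motif_sub_rate, spec.sub_rate)
    for i in range(1, spec.n_seqs):
        mutate = rng.random(L) < rates
        seq = list(template_str)
        for p in np.nonzero(mutate)[0]:
            probs, letters = dists[regions[p]]
            seq[p] = letters[int(rng.choice(len(letters), p=probs))]
        records.append(SequenceRecord(id=f"seq{i:03d}", residues="".join(seq)))

    family = set_reference(AlignedFamily(records=tuple(records)), "ref")
    truth = SyntheticTruth(
        template=template_str,
        tmd_bounds=tuple(tmd_bounds),
        loop_sides=tuple(_loop_side(h) for h in range(n + 1)),
        motif_positions=tuple(motif_positions),
    )
    return family, truth


def control_family(spec: FamilySpec) -> tuple[AlignedFamily, SyntheticTruth]:
    """The cytoplasmic-conservation control: motif sides flipped.

    Emulates ER enzymes whose catalytic face is cytoplasmic (a DPAGT1-like
    conservation pattern): every planted motif is moved to the neighbouring
    loop on the opposite side.  Flipping twice reproduces the original
    family bit-exactly at equal seed.
    """
    return generate(flip_spec(spec))


def flip_spec(spec: FamilySpec) -> FamilySpec:
    flipped = tuple(
        replace(pm, side="cytoplasmic" if pm.side == "luminal" else "luminal")
        for pm in spec.planted_motifs
    )
    return replace(spec, planted_motifs=flipped)


def write_family(
    family: AlignedFamily, truth: SyntheticTruth, directory: str | Path
) -> None:
    """Write the aligned FASTA plus the truth JSON into ``directory``."""
    from .seqio import write_alignment

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_alignment(family, directory / "family.fasta", "fasta")
    truth.to_json(directory / "truth.json")
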