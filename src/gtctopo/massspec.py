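"""Tryptic digestion and monoisotopic m/z of C-mannosylated peptides.

C-mannosylation attaches a single hexose (mannose, +162.052824 Da) to the
indole C2 of tryptophan.  For a tryptic glycopeptide carrying h hexoses the
observable ion is

    m/z = (M + h * 162.052824 + z * 1.007276) / z

with M the monoisotopic peptide mass (residue masses + water + fixed
modifications).  Cys carbamidomethylation (+57.021464 Da) is applied as a
fixed modification by default, the standard state of Cys in in-gel tryptic
digests; it can be disabled per peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

#: monoisotopic residue (amino-acid minus water) masses, Da
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER = 18.010565
PROTON = 1.007276
HEXOSE = 162.052824
CARBAMIDOMETHYL = 57.021464


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide with fixed mass modifications and a hexose count.

    ``fixed_mods`` lists (residue, mass delta) pairs applied to every
    occurrence of the residue; hexoses attach to Trp (mass-only — site
    localization within WxxW contexts is informational).
    """

    sequence: str
    fixed_mods: tuple[tuple[str, float], ...] = (("C", CARBAMIDOMETHYL),)
    variable_hexoses: int = 0
    charge: int = 1

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - set(RESIDUE_MASS)
        if bad:
            raise ValueError(f"unknown residue(s) {sorted(bad)!r}")
        if self.variable_hexoses < 0:
            raise ValueError("hexose count must be >= 0")
        if self.variable_hexoses > seq.count("W"):
            raise ValueError(
                f"{self.variable_hexoses} hexoses exceed {seq.count('W')} Trp"
            )
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


@dataclass(frozen=True)
class DigestPeptide:
    """A digestion product with 1-based inclusive parent coordinates."""

    sequence: str
    start: int
    end: int
    missed: int


def tryptic_digest(sequence: str, missed_cleavages: int = 0) -> list[DigestPeptide]:
    """In-silico trypsin digest: cleave after K/R except before P.

    Returns all peptides containing at most ``missed_cleavages`` internal
    cleavage sites, ordered by start then end.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    # cut points: index i means a cut between residue i and i+1 (1-based i)
    cuts = [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    bounds = [0] + cuts + [len(seq)]
    out: list[DigestPeptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            s, e = bounds[i], bounds[j]
            out.append(DigestPeptide(seq[s:e], s + 1, e, missed=j - i - 1))
    out.sort(key=lambda p: (p.start, p.end))
    return out


def monoisotopic_mass(p: ModifiedPeptide) -> float:
    """Monoisotopic mass in Da: residues + water + fixed mods + hexoses."""
    seq = p.sequence.upper()
    m = sum(RESIDUE_MASS[a] for a in seq) + WATER
    for residue, delta in p.fixed_mods:
        m += seq.count(residue.upper()) * delta
    m += p.variable_hexoses * HEXOSE
    return m


def mz(mass: float, z: int) -> float:
    """m/z of the [M+zH]z+ ion."""
    if z <= 0:
        raise ValueError("charge must be >= 1")
    return (mass + z * PROTON) / z


def hexose_ladder(
    peptide: str,
    max_hex: int,
    charges: Sequence[int],
    carbamidomethyl: bool = True,
):
    """Table of (hexoses, z, m/z) for 0..max_hex hexoses at each charge.

    ``max_hex`` may not exceed the peptide's Trp count.  Rows are ordered by
    hexose count then charge.
    """
    import pandas as pd

    seq = peptide.upper()
    if max_hex > seq.count("W"):
        raise ValueError(
            f"max_hex={max_hex} exceeds tryptophan count ({seq.count('W')})"
        )
    mods = (("C", CARBAMIDOMETHYL),) if carbamidomethyl else ()
    rows = []
    for h in range(max_hex + 1):
        p = ModifiedPeptide(seq, fixed_mods=mods, variable_hexoses=h)
        m = monoisotopic_mass(p)
        for z in charges:
            rows.append((h, z, m, mz(m, z)))
    return pd.DataFrame(rows, columns=["hexoses", "z", "mass", "mz"])
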