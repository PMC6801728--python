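"""Per-position conservation on reference coordinates.

Information content in bits, ``ic[p] = log2(20) - H(freq[p])``, computed
from residue frequencies with gaps and 'X' excluded from the denominator —
the convention of standard sequence logos computed on an alignment degapped
to a reference sequence.  Letter heights for logo export are
``freq * ic``, so each column's stack height equals its information
content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .seqio import AMINO_ACIDS, AlignedFamily

MAX_IC = float(np.log2(20.0))

#: default residue classes for conserved-position calls: acidic, basic and
#: amide pairs are treated as interchangeable, all other residues stand alone
DEFAULT_CLASSES: tuple[frozenset[str], ...] = tuple(
    [frozenset("DE"), frozenset("KR"), frozenset("NQ")]
    + [frozenset(a) for a in AMINO_ACIDS if a not in "DEKRNQ"]
)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class ConservationProfile:
    """Residue frequencies, information content and effective counts."""

    freq: np.ndarray    # (L, 20)
    ic: np.ndarray      # (L,) bits
    n_eff: np.ndarray   # (L,) contributing residues per column

    @property
    def length(self) -> int:
        return len(self.ic)

    def consensus(self) -> str:
        """Most frequent residue per position ('-' where no residue)."""
        out = []
        for p in range(self.length):
            if self.n_eff[p] == 0:
                out.append("-")
            else:
                out.append(AMINO_ACIDS[int(np.argmax(self.freq[p]))])
        return "".join(out)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "position": np.arange(1, self.length + 1),
                "ic": self.ic,
                "n_eff": self.n_eff,
                "consensus": list(self.consensus()),
            }
        )


def conservation_profile(
    family: AlignedFamily, small_sample_correction: bool = False
) -> ConservationProfile:
    """Column-wise frequencies and information content for a degapped family.

    Positions where every sequence is gapped get ``ic = 0`` and
    ``n_eff = 0``.  With ``small_sample_correction`` the usual
    ``(s-1)/(2 ln 2 n)`` correction (s = 20) is subtracted and clipped at 0;
    it is off by default to match standard logo output at family sizes of
    25-30 sequences.
    """
    if family.n == 1:
        warnings.warn(
            "conservation profile of a single sequence is maximal by definition",
            stacklevel=2,
        )
    L = family.length
    freq = np.zeros((L, 20))
    n_eff = np.zeros(L, dtype=int)
    ic = np.zeros(L)
    for p in range(L):
        counts = np.zeros(20)
        for a in family.column(p):
            i = _AA_INDEX.get(a)
            if i is not None:
                counts[i] += 1
        total = counts.sum()
        n_eff[p] = int(total)
        if total == 0:
            continue
        f = counts / total
        freq[p] = f
        nz = f[f > 0]
        h = float(-(nz * np.log2(nz)).sum())
        val = MAX_IC - h
        if small_sample_correction and total > 0:
            val -= 19.0 / (2.0 * np.log(2.0) * total)
        ic[p] = max(0.0, val)
    return ConservationProfile(freq=freq, ic=ic, n_eff=n_eff)


def call_conserved(
    profile: ConservationProfile,
    mode: str = "class_freq",
    cutoff: float = 0.8,
    classes: Iterable[frozenset[str]] = DEFAULT_CLASSES,
) -> set[int]:
    """Call conserved positions (1-based) by information content or class frequency.

    ``mode='ic'``: positions with ``ic >= cutoff`` (bits).
    ``mode='class_freq'``: positions where one residue class (acidic D/E,
    basic K/R, amide N/Q merged by default) reaches combined frequency
    >= cutoff.
    """
    if mode == "ic":
        if not 0 <= cutoff <= MAX_IC:
            raise ValueError(f"ic cutoff must be within [0, {MAX_IC:.4f}]")
        return {p + 1 for p in range(profile.length) if profile.ic[p] >= cutoff}
    if mode == "class_freq":
        if not 0 < cutoff <= 1:
            raise ValueError("class_freq cutoff must be in (0, 1]")
        class_idx = [[_AA_INDEX[a] for a in cl] for cl in classes]
        called = set()
        for p in range(profile.length):
            if profile.n_eff[p] == 0:
                continue
            if any(profile.freq[p, idx].sum() >= cutoff for idx in class_idx):
                called.add(p + 1)
        return called
    raise ValueError(f"unknown mode {mode!r}")


def dominant_class(
    profile: ConservationProfile,
    position: int,
    classes: Iterable[frozenset[str]] = DEFAULT_CLASSES,
) -> tuple[frozenset[str], float]:
    """The residue class with the largest combined frequency at a position."""
    best, best_f = frozenset(), -1.0
    for cl in classes:
        f = float(profile.freq[position - 1, [_AA_INDEX[a] for a in cl]].sum())
        if f > best_f:
            best, best_f = cl, f
    return best, best_f


def logo_matrix(profile: ConservationProfile):
    """Letter heights (freq x ic) as a long DataFrame for TSV export.

    Zero-height letters are omitted; per-position height sums equal ic.
    """
    import pandas as pd

    rows = []
    for p in range(profile.length):
        for i, a in enumerate(AMINO_ACIDS):
            h = profile.freq[p, i] * profile.ic[p]
            if h > 0:
                rows.append((p + 1, a, h))
    return pd.DataFrame(rows, columns=["position", "residue", "height"])
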