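"""Family-level topology model assembly and the conservation asymmetry test.

The organization string ("1-8-4", "1-6-4", ...) partitions a family's
helices at its large luminal loops: first helix, central cluster, and the
C-terminal cluster (extended when extra C-terminal helices are present).
The asymmetry test quantifies the observation that catalytic conservation
sits in luminal, not cytoplasmic, loops: the statistic is the difference of
mean per-position information content between luminal and cytoplasmic loop
residues, and significance comes from a permutation null that reassigns
whole-loop side labels, preserving within-loop correlation of conservation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .conservation import ConservationProfile, call_conserved
from .motifs import FamilyEntry, MotifHit, assign_loops
from .seqio import AlignedFamily
from .topology import TopologyModel


class InsufficientStructureError(ValueError):
    """Raised when a model lacks the loops needed for the asymmetry test."""


@dataclass(frozen=True)
class AsymmetryResult:
    """Luminal-minus-cytoplasmic mean conservation, with permutation p."""

    statistic: float  # bits
    n_perm: int
    p_value: float
    seed: int


@dataclass
class FamilyModelReport:
    """The assembled per-family result with cross-check flags."""

    family: str
    n_tmds: int
    organization: str
    n_term_side: str
    c_term_side: str
    orientation_rule: str
    segments: list[tuple[int, int, int]]  # (helix, start, end)
    hits: list[MotifHit]
    conserved_positions: dict[str, list[int]]  # side -> positions
    asymmetry: Optional[AsymmetryResult]
    flags: list[str]
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "n_tmds": self.n_tmds,
            "organization": self.organization,
            "n_term_side": self.n_term_side,
            "c_term_side": self.c_term_side,
            "orientation_rule": self.orientation_rule,
            "segments": [list(s) for s in self.segments],
            "hits": [asdict(h) for h in self.hits],
            "conserved_positions": self.conserved_positions,
            "asymmetry": asdict(self.asymmetry) if self.asymmetry else None,
            "flags": list(self.flags),
            "config": self.config,
        }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def summary_frame(self):
        """Flat one-row summary for TSV export."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "family": self.family,
                    "n_tmds": self.n_tmds,
                    "organization": self.organization,
                    "n_term_side": self.n_term_side,
                    "c_term_side": self.c_term_side,
                    "n_hits": len(self.hits),
                    "asymmetry_statistic": (
                        self.asymmetry.statistic if self.asymmetry else np.nan
                    ),
                    "asymmetry_p": self.asymmetry.p_value if self.asymmetry else np.nan,
                    "n_flags": len(self.flags),
                    "flags": ";".join(self.flags),
                }
            ]
        )


# ---------------------------------------------------------------------------
# organization


def organization_string(model: TopologyModel, large_loop_min: int = 40) -> str:
    """Partition helices at large luminal loops into an "a-b-c[-d]" string.

    Only inter-helix loops count as landmarks (termini are not partition
    points); a loop qualifies when it is luminal and at least
    ``large_loop_min`` residues long.
    """
    if model.n_tmds < 3:
        return "n/a"
    parts: list[int] = []
    current = 1
    loops = model.loops()[1:-1]  # inter-helix loops, one after each helix i<n
    for lp in loops:
        if lp.side == "luminal" and lp.length >= large_loop_min:
            parts.append(current)
            current = 0
        current += 1
    parts.append(current)
    return "-".join(str(p) for p in parts)


# ---------------------------------------------------------------------------
# asymmetry test


def asymmetry_test(
    model: TopologyModel,
    profile: ConservationProfile,
    n_perm: int = 1000,
    seed: int = 0,
) -> AsymmetryResult:
    """Permutation test of luminal-vs-cytoplasmic loop conservation.

    Statistic: mean information content over luminal-loop positions minus
    the same over cytoplasmic-loop positions (helix positions excluded;
    termini included).  The null redistributes the observed side labels
    over loops uniformly at random (alternation is deliberately dropped),
    so within-loop autocorrelation of conservation is preserved.  The
    one-sided p-value carries the +1 correction.
    """
    if model.length != profile.length:
        raise ValueError(
            f"model length {model.length} != profile length {profile.length}"
        )
    loops = [lp for lp in model.loops() if lp.length > 0]
    sides = np.array([lp.side == "luminal" for lp in loops])
    if sides.sum() < 2 or (~sides).sum() < 2:
        raise InsufficientStructureError(
            "need at least 2 non-empty loops on each membrane side"
        )
    sums = np.array(
        [profile.ic[lp.start - 1 : lp.end].sum() for lp in loops]
    )
    counts = np.array([lp.length for lp in loops], dtype=float)

    def stat(mask: np.ndarray) -> float:
        return float(
            sums[mask].sum() / counts[mask].sum()
            - sums[~mask].sum() / counts[~mask].sum()
        )

    observed = stat(sides)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(sides)
        if stat(perm) >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return AsymmetryResult(
        statistic=observed, n_perm=n_perm, p_value=p, seed=seed
    )


# ---------------------------------------------------------------------------
# report assembly


def build_report(
    family_name: str,
    family: AlignedFamily,
    model: TopologyModel,
    profile: ConservationProfile,
    hits: Sequence[MotifHit],
    entry: Optional[FamilyEntry] = None,
    large_loop_min: int = 40,
    conserved_cutoff: float = 0.8,
    n_perm: int = 1000,
    seed: int = 0,
    config: Optional[dict] = None,
) -> FamilyModelReport:
    """Assemble the annotated family model and run its cross-checks.

    Flags raised: observed-vs-expected helix count mismatches, library
    motifs found on the wrong membrane side, a dilysine signal on a
    non-cytoplasmic C-terminus, and expected motifs that were not found.
    """
    ref_len = len(family.reference.ungapped())
    if model.length != ref_len or profile.length != ref_len:
        raise ValueError("family, model and profile must share the reference length")

    labelled = assign_loops(list(hits), model)

    flags: list[str] = []
    if entry is not None and entry.n_tmds != model.n_tmds:
        flags.append(
            f"tmd-count-mismatch: expected {entry.n_tmds}, observed {model.n_tmds}"
        )

    from .motifs import library as motif_library

    lib = motif_library()
    found_names = set()
    for h in labelled:
        found_names.add(h.name)
        pat = lib.get(h.name)
        if pat is None or pat.expected_side == "either" or h.side is None:
            continue
        if h.side != pat.expected_side:
            flags.append(
                f"motif-side-mismatch: {h.name} at {h.start}-{h.end} on "
                f"{h.side}, expected {pat.expected_side}"
            )
    dilysine_hits = [h for h in labelled if h.name == "dilysine"]
    for h in dilysine_hits:
        if h.side != "cytoplasmic":
            flags.append("dilysine-not-cytoplasmic")
    if entry is not None:
        if entry.dilysine and not dilysine_hits:
            flags.append("dilysine-expected-not-found")
        for name in entry.expected_motifs:
            if name in entry.absent_motifs:
                continue
            if lib.get(name) is not None and lib[name].conserved_position:
                continue  # evaluated via conservation calls below
            if name not in found_names:
                flags.append(f"motif-not-found: {name}")

    # conserved positions by membrane side (helix positions excluded)
    conserved = call_conserved(profile, mode="class_freq", cutoff=conserved_cutoff)
    masks = model.side_mask()
    by_side = {
        side: sorted(p for p in conserved if masks[side][p - 1])
        for side in ("luminal", "cytoplasmic")
    }

    try:
        asym = asymmetry_test(model, profile, n_perm=n_perm, seed=seed)
    except InsufficientStructureError:
        asym = None
        flags.append("asymmetry-not-applicable")

    cfg = {
        "large_loop_min": large_loop_min,
        "conserved_cutoff": conserved_cutoff,
        "n_perm": n_perm,
        "seed": seed,
    }
    if config:
        cfg.update(config)

    return FamilyModelReport(
        family=family_name,
        n_tmds=model.n_tmds,
        organization=organization_string(model, large_loop_min),
        n_term_side=model.n_term_side,
        c_term_side=model.c_term_side,
        orientation_rule=model.decided_by,
        segments=[(s.index, s.start, s.end) for s in model.segments],
        hits=labelled,
        conserved_positions=by_side,
        asymmetry=asym,
        flags=flags,
        config=cfg,
    )
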