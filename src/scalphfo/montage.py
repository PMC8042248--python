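"""Bipolar neighbour montage for the international 10-20 electrode set.

The 19 scalp electrodes are laid out on a 5-row grid; two electrodes are
neighbours when they are adjacent on the grid (8-connectivity, i.e. including
diagonals) or form one of the two physically adjacent cross-row pairs Fp1-Fp2
and O1-O2.  This yields exactly 52 bipolar derivations and contains every
"channel with highest HFO rate" reported in scalp ripple studies on this
montage (including the diagonal derivations such as T5-C3, F3-Cz, Pz-O2).

The pair list ships as ``data/montage_pairs.tsv`` and is re-derived from the
grid in the test suite so the file and the rule cannot drift apart.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .types import MontageError, Recording

__all__ = [
    "GRID",
    "MONTAGE_ELECTRODES",
    "BipolarChannel",
    "montage_pairs",
    "derive_pairs_from_grid",
    "canonical_pair_name",
    "normalize_label",
    "mirror_electrode",
    "homologue_map",
    "make_bipolar_montage",
]

# (row, column) positions; columns 0..4 run left to right, row 0 is frontal.
GRID: dict[str, tuple[int, int]] = {
    "Fp1": (0, 1), "Fp2": (0, 3),
    "F7": (1, 0), "F3": (1, 1), "Fz": (1, 2), "F4": (1, 3), "F8": (1, 4),
    "T3": (2, 0), "C3": (2, 1), "Cz": (2, 2), "C4": (2, 3), "T4": (2, 4),
    "T5": (3, 0), "P3": (3, 1), "Pz": (3, 2), "P4": (3, 3), "T6": (3, 4),
    "O1": (4, 1), "O2": (4, 3),
}

# Cross-row pairs that are physically adjacent despite a grid column gap.
_EXTRA_PAIRS = [("Fp1", "Fp2"), ("O1", "O2")]

MONTAGE_ELECTRODES: list[str] = sorted(GRID, key=lambda e: GRID[e])

_ELECTRODE_INDEX = {e: i for i, e in enumerate(MONTAGE_ELECTRODES)}

# Alias table for vendor label styles; modern temporal names map to the
# classical 10-20 names used throughout.
_ALIASES = {
    "T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6",
}
_CANONICAL_BY_UPPER = {e.upper(): e for e in MONTAGE_ELECTRODES}
_CANONICAL_BY_UPPER.update({k.upper(): v for k, v in _ALIASES.items()})


def normalize_label(raw: str) -> str | None:
    """Map a vendor channel label onto a 10-20 electrode name.

    Handles prefixes like ``"EEG Fp1-Ref"`` and case variants (``"FP1"``).
    Returns None for labels that do not correspond to a montage electrode.
    """
    s = raw.strip()
    s = re.sub(r"^(EEG|eeg)[ _:]+", "", s)
    s = re.sub(r"[-_ ](REF|Ref|ref|LE|RE|A1|A2|AVG|M1|M2)$", "", s)
    return _CANONICAL_BY_UPPER.get(s.strip().upper())


@dataclass(frozen=True)
class BipolarChannel:
    """A bipolar derivation; signal = anode - cathode, sample-wise."""

    anode: str
    cathode: str

    @property
    def name(self) -> str:
        return f"{self.anode}-{self.cathode}"

    @property
    def electrodes(self) -> frozenset[str]:
        return frozenset((self.anode, self.cathode))


def derive_pairs_from_grid() -> list[BipolarChannel]:
    """All neighbouring electrode pairs under the grid adjacency rule."""
    pairs: set[tuple[str, str]] = set()
    for a, (ra, ca) in GRID.items():
        for b, (rb, cb) in GRID.items():
            if a != b and max(abs(ra - rb), abs(ca - cb)) == 1:
                pairs.add(tuple(sorted((a, b), key=_ELECTRODE_INDEX.get)))
    pairs.update(_EXTRA_PAIRS)
    ordered = sorted(pairs, key=lambda p: (_ELECTRODE_INDEX[p[0]], _ELECTRODE_INDEX[p[1]]))
    return [BipolarChannel(a, b) for a, b in ordered]


def montage_pairs() -> list[BipolarChannel]:
    """The published 52-pair adjacency list shipped with the package."""
    text = resources.files("scalphfo.data").joinpath("montage_pairs.tsv").read_text()
    out = []
    for line in text.strip().splitlines()[1:]:
        a, b = line.split("\t")
        out.append(BipolarChannel(a, b))
    return out


def canonical_pair_name(name: str) -> str:
    """Canonicalize a pair label: both electrode orders are accepted on input
    (published tables mix them, e.g. "T3-F3" vs "F3-T3"); internally the
    anterior/left electrode comes first, following the grid order."""
    parts = name.split("-")
    if len(parts) != 2:
        raise MontageError(f"not a bipolar channel name: {name!r}")
    elecs = []
    for p in parts:
        e = normalize_label(p)
        if e is None:
            raise MontageError(f"unknown electrode {p!r} in {name!r}")
        elecs.append(e)
    a, b = sorted(elecs, key=_ELECTRODE_INDEX.get)
    return f"{a}-{b}"


def mirror_electrode(e: str) -> str:
    """Left-right homologue of an electrode; midline electrodes self-map."""
    row, col = GRID[e]
    target = (row, 4 - col)
    for other, pos in GRID.items():
        if pos == target:
            return other
    return e


def homologue_map(pairs: list[BipolarChannel] | None = None) -> dict[str, str]:
    """Map each bipolar channel name to its left-right mirror derivation.

    Midline-only pairs (e.g. Fz-Cz) and cross-hemisphere pairs that mirror
    onto themselves (Fp1-Fp2, O1-O2) are omitted: they have no distinct
    partner, hence no bilateral co-occurrence check applies.
    """
    if pairs is None:
        pairs = montage_pairs()
    names = {p.name for p in pairs}
    out: dict[str, str] = {}
    for p in pairs:
        mirrored = canonical_pair_name(
            f"{mirror_electrode(p.anode)}-{mirror_electrode(p.cathode)}"
        )
        if mirrored != p.name and mirrored in names:
            out[p.name] = mirrored
    return out


def make_bipolar_montage(
    rec: Recording,
) -> tuple[list[BipolarChannel], np.ndarray]:
    """Build the bipolar neighbour montage from a referential recording.

    Returns the induced sub-montage (pairs whose both electrodes are present)
    and the derived signals, one row per pair, ``anode - cathode``.
    """
    present = {normalize_label(lab): i for i, lab in enumerate(rec.labels)}
    present.pop(None, None)
    if len(present) < 2:
        raise MontageError("need at least 2 montage electrodes")
    pairs = [p for p in montage_pairs() if p.anode in present and p.cathode in present]
    if not pairs:
        raise MontageError("no adjacent electrode pair among usable channels")
    signals = np.empty((len(pairs), rec.n_times))
    for i, p in enumerate(pairs):
        signals[i] = rec.samples[present[p.anode]] - rec.samples[present[p.cathode]]
    return pairs, signals
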