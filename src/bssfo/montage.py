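"""Electrode montages and Laplacian neighbor maps.

Surface-Laplacian derivations subtract the mean of an electrode's nearest
neighbors from the electrode itself, acting as a spatial high-pass that
sharpens focal sensorimotor rhythms.  Neighbor sets are derived from an
idealized 10-10 electrode lattice: each cap position sits on a (row, column)
grid and its Laplacian neighbors are the four lattice-adjacent positions
(fewer at the cap edge).  The exact neighbor assignments on a real cap vary
with the physical montage; these maps are a stated approximation and can be
overridden by supplying a custom :class:`MontageSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# Rows of the 10-10 lattice, frontal to occipital.  Column index: odd digits
# are left hemisphere, even digits right, 'z' the midline; digit n maps to
# lateral offset +-ceil(n/2).
_ROWS = ["Fp", "AF", "F", "FC", "C", "CP", "P", "PO", "O"]

# Columns present per row on a typical 10-10 cap (by lateral offset).
_ROW_COLS = {
    "Fp": [-1, 0, 1],
    "AF": [-2, -1, 0, 1, 2],
    "F": [-4, -3, -2, -1, 0, 1, 2, 3, 4],
    "FC": [-4, -3, -2, -1, 0, 1, 2, 3, 4],
    "C": [-4, -3, -2, -1, 0, 1, 2, 3, 4],
    "CP": [-4, -3, -2, -1, 0, 1, 2, 3, 4],
    "P": [-4, -3, -2, -1, 0, 1, 2, 3, 4],
    "PO": [-2, -1, 0, 1, 2],
    "O": [-1, 0, 1],
}


def _name(row: str, col: int) -> str:
    if col == 0:
        return f"{row}z"
    digit = 2 * abs(col) - (1 if col < 0 else 0)
    return f"{row}{digit}"


def _lattice() -> dict[str, tuple[int, int]]:
    pos = {}
    for r, row in enumerate(_ROWS):
        for col in _ROW_COLS[row]:
            pos[_name(row, col)] = (r, col)
    return pos


_POSITIONS = _lattice()


def channel_position(name: str) -> tuple[int, int]:
    """(row, lateral offset) of a 10-10 channel on the idealized lattice."""
    try:
        return _POSITIONS[name]
    except KeyError:
        raise KeyError(f"unknown 10-10 channel label: {name!r}") from None


def lattice_neighbors(name: str) -> list[str]:
    """Lattice-adjacent cap positions (up to 4; fewer at the cap edge)."""
    r, c = channel_position(name)
    out = []
    for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
        if 0 <= rr < len(_ROWS) and cc in _ROW_COLS[_ROWS[rr]]:
            out.append(_name(_ROWS[rr], cc))
    return out


@dataclass
class MontageSpec:
    """A named set of Laplacian derivations: center channel -> neighbors."""

    name: str
    laplacian_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for center, neigh in self.laplacian_map.items():
            if not neigh:
                raise ValueError(f"empty neighbor list for center {center!r}")

    @property
    def centers(self) -> list[str]:
        return list(self.laplacian_map)

    def required_channels(self) -> list[str]:
        """All channels a recording must contain, centers first."""
        seen = dict.fromkeys(self.laplacian_map)
        for neigh in self.laplacian_map.values():
            seen.update(dict.fromkeys(neigh))
        return list(seen)


# Montage center sets.  The 3-channel arrangement covers the hand/foot motor
# strip; the 16-channel arrangement the sensorimotor cortex; the 39-channel
# arrangement most of the cap.
_CENTERS_3 = ["C3", "Cz", "C4"]
_CENTERS_16 = [
    "FC3", "FC1", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
]
_CENTERS_39 = (
    ["F3", "F1", "Fz", "F2", "F4"]
    + [_name("FC", c) for c in range(-3, 4)]
    + [_name("C", c) for c in range(-3, 4)]
    + [_name("CP", c) for c in range(-3, 4)]
    + [_name("P", c) for c in range(-3, 4)]
    + ["PO3", "POz", "PO4", "O1", "Oz", "O2"]
)

_STANDARD = {"3lap": _CENTERS_3, "16lap": _CENTERS_16, "39lap": _CENTERS_39}


def standard_montage(name: str) -> MontageSpec:
    """One of the shipped Laplacian montages: ``3lap``, ``16lap``, ``39lap``."""
    key = name.lower()
    if key not in _STANDARD:
        raise KeyError(f"unknown montage {name!r}; available: {sorted(_STANDARD)}")
    lap = {c: lattice_neighbors(c) for c in _STANDARD[key]}
    return MontageSpec(name=key, laplacian_map=lap)
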