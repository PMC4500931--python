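"""Electrode geometry for a two-well microtunnel device on an 8x8 MEA.

The device sits over a standard 8x8 grid of substrate electrodes with
200 um pitch.  The four grid corners carry no electrode and one position
is used as the on-chip reference, leaving 59 recording electrodes.  Two
of the eight rows lie beneath the microtunnel bridge that couples the
wells; the three rows on either side lie inside Well A and Well B
respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GRID_SIZE = 8
PITCH_UM = 200.0
#: grid positions without an electrode: the four corners
_CORNERS = {(1, 1), (1, 8), (8, 1), (8, 8)}
#: the reference electrode position (column 1, row 5), omitted from recording
_REFERENCE = (1, 5)

REGION_A = "A"
REGION_TUNNEL = "tunnel"
REGION_B = "B"
REGIONS = (REGION_A, REGION_TUNNEL, REGION_B)

#: rows belonging to each region: 3 well rows, 2 tunnel rows, 3 well rows
ROW_REGIONS = {
    1: REGION_A, 2: REGION_A, 3: REGION_A,
    4: REGION_TUNNEL, 5: REGION_TUNNEL,
    6: REGION_B, 7: REGION_B, 8: REGION_B,
}


@dataclass(frozen=True)
class Electrode:
    """One recording site: MCS-style id ``"<col><row>"`` plus grid metadata."""

    id: str
    col: int
    row: int
    region: str
    x_um: float
    y_um: float
    excluded: bool = False


@dataclass(frozen=True)
class ElectrodeLayout:
    """Immutable electrode map partitioning ids into Well A / tunnel / Well B."""

    electrodes: tuple[Electrode, ...]
    _by_id: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        by_id = {e.id: e for e in self.electrodes}
        if len(by_id) != len(self.electrodes):
            raise ValueError("electrode ids must be unique")
        object.__setattr__(self, "_by_id", by_id)

    def __len__(self) -> int:
        return len(self.electrodes)

    def __contains__(self, eid: str) -> bool:
        return eid in self._by_id

    def __getitem__(self, eid: str) -> Electrode:
        return self._by_id[eid]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(e.id for e in self.electrodes)

    def region_of(self, eid: str) -> str:
        return self._by_id[eid].region

    def region_ids(self, region: str, include_excluded: bool = False) -> tuple[str, ...]:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
        return tuple(
            e.id for e in self.electrodes
            if e.region == region and (include_excluded or not e.excluded)
        )

    def with_excluded(self, ids) -> "ElectrodeLayout":
        """Return a copy with the given electrode ids flagged excluded."""
        ids = set(ids)
        missing = ids - set(self.ids)
        if missing:
            raise KeyError(f"unknown electrode ids: {sorted(missing)}")
        elecs = tuple(
            Electrode(e.id, e.col, e.row, e.region, e.x_um, e.y_um,
                      excluded=e.excluded or e.id in ids)
            for e in self.electrodes
        )
        return ElectrodeLayout(elecs)


def electrode_id(col: int, row: int) -> str:
    return f"{col}{row}"


def default_layout() -> ElectrodeLayout:
    """The 59-electrode two-well layout: rows 1-3 Well A, 4-5 tunnels, 6-8 Well B."""
    elecs = []
    for col in range(1, GRID_SIZE + 1):
        for row in range(1, GRID_SIZE + 1):
            if (col, row) in _CORNERS or (col, row) == _REFERENCE:
                continue
            elecs.append(Electrode(
                id=electrode_id(col, row),
                col=col,
                row=row,
                region=ROW_REGIONS[row],
                x_um=(col - 1) * PITCH_UM,
                y_um=(row - 1) * PITCH_UM,
            ))
    return ElectrodeLayout(tuple(elecs))


#: default stimulation site: outer Well-A row, central column (furthest from tunnels)
DEFAULT_STIM_ELECTRODE = "41"
#: mirror-image site used when the device is plated in the reverse direction
DEFAULT_STIM_ELECTRODE_REVERSE = "48"
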