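"""Back-of-envelope device arithmetic: cell counts, axon counts, wave speeds.

These reproduce the order-of-magnitude estimates used to interpret the
dose-response measurements: a 20 mm^2 well plated at ~1500 cells/mm^2 holds
30,000 neurons; ten 3 x 10 um tunnels at ~10 axons each carry ~100 axons,
i.e. ~0.3% of the downstream population; and 1 mm well-to-well propagation
at 100-300 ms delay corresponds to 3.3-10 mm/s burst-wave speeds.
"""

from __future__ import annotations

WELL_AREA_MM2 = 20.0
CELL_DENSITY_PER_MM2 = 1500.0
AXONS_PER_TUNNEL = 10.0
WELL_TO_WELL_DISTANCE_MM = 1.0


def cells_per_well(area_mm2: float = WELL_AREA_MM2,
                   density_per_mm2: float = CELL_DENSITY_PER_MM2) -> float:
    """Total neurons in one well: culture area times plating density."""
    if area_mm2 <= 0 or density_per_mm2 <= 0:
        raise ValueError("area and density must be positive")
    return area_mm2 * density_per_mm2


def axon_count(n_tunnels: int, axons_per_tunnel: float = AXONS_PER_TUNNEL) -> float:
    """Estimated axons crossing between wells."""
    if n_tunnels < 0 or axons_per_tunnel < 0:
        raise ValueError("counts must be non-negative")
    return n_tunnels * axons_per_tunnel


def axon_to_cell_ratio_percent(n_axons: float, n_cells: float) -> float:
    """Connecting axons as a percentage of the downstream population."""
    if n_cells <= 0:
        raise ValueError("cell count must be positive")
    return 100.0 * n_axons / n_cells


def propagation_speed_mm_per_s(delay_ms: float,
                               distance_mm: float = WELL_TO_WELL_DISTANCE_MM) -> float:
    """Burst-wave speed implied by a well-to-well delay."""
    if delay_ms <= 0 or distance_mm <= 0:
        raise ValueError("delay and distance must be positive")
    return distance_mm / (delay_ms / 1e3)
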