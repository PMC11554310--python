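"""Plex layout computation for multiplexed thermal-shift screens.

Compounds are assayed in replicate within a single TMT plex (fold changes
are taken against the vehicle channels of the same plex), so a 16-plex with
v vehicle channels holds (16 - v) // r compounds at r replicates each.
A 96-compound duplicate screen with 4 vehicle channels per plex therefore
fills 16 plexes (256 channels); a 70-compound duplicate screen with 2
vehicle channels per plex fills 10 plexes (160 channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .quant_io import VEHICLE_TREATMENT

__all__ = ["PlexLayout", "design_layout"]


@dataclass
class PlexLayout:
    """Channel-level assignment of treatments to plexes.

    ``channels`` has one row per channel: channel_id, plex_id, treatment_id,
    replicate_index, is_vehicle.  ``n_padding_vehicle`` counts spare channels
    (beyond the designed vehicle count) filled with extra vehicle controls in
    a final, partially filled plex.
    """

    channels: pd.DataFrame
    n_plexes: int
    plex_size: int
    n_padding_vehicle: int = 0

    @property
    def total_channels(self) -> int:
        return self.n_plexes * self.plex_size

    def vehicle_channels(self, plex_id: str) -> list[str]:
        ch = self.channels
        sel = (ch["plex_id"] == plex_id) & ch["is_vehicle"]
        return ch.loc[sel, "channel_id"].tolist()


def design_layout(
    n_compounds: int,
    replicates: int = 2,
    plex_size: int = 16,
    vehicle_per_plex: int = 4,
    compound_ids: list[str] | None = None,
) -> PlexLayout:
    """Assign compounds (in replicate) and vehicle controls to plexes.

    Both replicates of a compound land in the same plex and every plex
    carries at least ``vehicle_per_plex`` vehicle channels (>= 2 required).
    If the compounds do not tile the final plex exactly, its spare channels
    are filled with extra vehicle controls and reported via
    ``n_padding_vehicle``.
    """
    if n_compounds < 1:
        raise ValueError("need at least one compound")
    if vehicle_per_plex < 2:
        raise ValueError("every plex needs at least two vehicle channels")
    per_plex = (plex_size - vehicle_per_plex) // replicates
    if per_plex < 1:
        raise ValueError(
            f"infeasible geometry: {replicates} replicates + {vehicle_per_plex} vehicle "
            f"channels cannot fit a {plex_size}-plex"
        )
    if compound_ids is None:
        width = len(str(n_compounds))
        compound_ids = [f"cmpd{str(i + 1).zfill(width)}" for i in range(n_compounds)]
    elif len(compound_ids) != n_compounds:
        raise ValueError("compound_ids length must equal n_compounds")

    n_plexes = -(-n_compounds // per_plex)  # ceil
    rows = []
    n_padding = 0
    pw = len(str(n_plexes))
    for p in range(n_plexes):
        plex = f"plex{str(p + 1).zfill(pw)}"
        cmpds = compound_ids[p * per_plex : (p + 1) * per_plex]
        ch = 0
        for c in cmpds:
            for r in range(1, replicates + 1):
                ch += 1
                rows.append((f"{plex}_ch{ch:02d}", plex, c, r, False))
        n_veh = plex_size - ch
        n_padding += max(0, n_veh - vehicle_per_plex)
        for r in range(1, n_veh + 1):
            ch += 1
            rows.append((f"{plex}_ch{ch:02d}", plex, VEHICLE_TREATMENT, r, True))
    channels = pd.DataFrame(
        rows, columns=["channel_id", "plex_id", "treatment_id", "replicate_index", "is_vehicle"]
    )
    return PlexLayout(channels=channels, n_plexes=n_plexes, plex_size=plex_size,
                      n_padding_vehicle=n_padding)
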