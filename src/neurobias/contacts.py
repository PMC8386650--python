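"""Ligand-residue polar contact frequencies, direct and water-mediated.

Input is a plain per-frame coordinate table (columns: frame, atom_id, role,
x, y, z in Angstrom) rather than a binary trajectory format.  A pair is in
*direct* contact when the Euclidean distance between the two atoms is at most
the cutoff (closed interval; default 3.5 A heavy-atom donor-acceptor), and in
*water-mediated* contact when some water oxygen lies within the cutoff of
both partners.  A frame counts at most once per pair regardless of how many
routes (direct plus any number of bridges) connect it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContactFrequencyMap",
    "direct_contact",
    "water_mediated_contact",
    "contact_frequencies",
]


@dataclass(frozen=True)
class ContactFrequencyMap:
    """Per-pair contact frequencies over a trajectory.

    ``table`` has one row per pair with columns ``atom_a, atom_b, frequency,
    direct_frequency, water_mediated_frequency`` (the last counts frames where
    only a water bridge connects the pair; direct + water_only = any).
    """

    table: pd.DataFrame
    n_frames: int
    cutoff: float

    def matrix(self) -> pd.DataFrame:
        """Pivot to an atom_a x atom_b frequency matrix (heatmap-ready)."""
        return self.table.pivot(index="atom_a", columns="atom_b", values="frequency")


def _coords_for(frame_df: pd.DataFrame, atom_id) -> np.ndarray:
    rows = frame_df.loc[frame_df["atom_id"] == atom_id, ["x", "y", "z"]]
    if rows.empty:
        raise ValueError(f"atom {atom_id!r} missing from frame")
    return rows.to_numpy(float)[0]


def direct_contact(frame_df: pd.DataFrame, pairs: Sequence[tuple], cutoff: float = 3.5):
    """Boolean per pair: distance(atom_a, atom_b) <= cutoff in this frame."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    out = np.empty(len(pairs), dtype=bool)
    for i, (a, b) in enumerate(pairs):
        ca, cb = _coords_for(frame_df, a), _coords_for(frame_df, b)
        if not (np.all(np.isfinite(ca)) and np.all(np.isfinite(cb))):
            raise ValueError(f"non-finite coordinates for pair ({a!r}, {b!r})")
        out[i] = np.linalg.norm(ca - cb) <= cutoff
    return out


def water_mediated_contact(
    frame_df: pd.DataFrame,
    pair: tuple,
    cutoff: float = 3.5,
    water_role: str = "water",
) -> bool:
    """True iff some water is within ``cutoff`` of *both* pair partners."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    a, b = pair
    ca, cb = _coords_for(frame_df, a), _coords_for(frame_df, b)
    waters = frame_df.loc[frame_df["role"] == water_role, ["x", "y", "z"]].to_numpy(float)
    if waters.size == 0:
        return False
    da = np.linalg.norm(waters - ca, axis=1)
    db = np.linalg.norm(waters - cb, axis=1)
    return bool(np.any((da <= cutoff) & (db <= cutoff)))


def contact_frequencies(
    frames: pd.DataFrame,
    pairs: Sequence[tuple],
    cutoff: float = 3.5,
    include_water: bool = False,
    water_role: str = "water",
) -> ContactFrequencyMap:
    """Contact frequency per pair: frames-with-contact / n_frames.

    With ``include_water`` a frame counts when the pair is in direct *or*
    water-mediated contact (never double-counted).  Deterministic; raises on
    an empty table.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if frames.empty:
        raise ValueError("no frames in coordinate table")
    frame_ids = frames["frame"].unique()
    n_frames = frame_ids.size

    # direct path vectorized: coordinates per atom across frames
    pivot = frames.pivot_table(index="frame", columns="atom_id", values=["x", "y", "z"])
    direct_counts = np.zeros(len(pairs), dtype=int)
    for i, (a, b) in enumerate(pairs):
        for atom in (a, b):
            if ("x", atom) not in pivot.columns:
                raise ValueError(f"atom {atom!r} missing from coordinate table")
        ca = pivot.loc[:, [("x", a), ("y", a), ("z", a)]].to_numpy(float)
        cb = pivot.loc[:, [("x", b), ("y", b), ("z", b)]].to_numpy(float)
        if np.isnan(ca).any() or np.isnan(cb).any():
            raise ValueError(f"atoms of pair ({a!r}, {b!r}) missing from some frames")
        d = np.linalg.norm(ca - cb, axis=1)
        direct_counts[i] = int(np.sum(d <= cutoff))

    water_only_counts = np.zeros(len(pairs), dtype=int)
    any_counts = direct_counts.copy()
    if include_water:
        any_counts = np.zeros(len(pairs), dtype=int)
        for fid, frame_df in frames.groupby("frame", sort=False):
            direct = direct_contact(frame_df, pairs, cutoff)
            for i, pair in enumerate(pairs):
                if direct[i]:
                    any_counts[i] += 1
                elif water_mediated_contact(frame_df, pair, cutoff, water_role):
                    any_counts[i] += 1
                    water_only_counts[i] += 1

    table = pd.DataFrame(
        {
            "atom_a": [p[0] for p in pairs],
            "atom_b": [p[1] for p in pairs],
            "frequency": any_counts / n_frames,
            "direct_frequency": direct_counts / n_frames,
            "water_mediated_frequency": water_only_counts / n_frames,
        }
    )
    return ContactFrequencyMap(table=table, n_frames=int(n_frames), cutoff=float(cutoff))
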