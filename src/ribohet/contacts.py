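"""RP contact sets and circular-shift background sets.

A residue is a contact point of an RP when its minimum distance to that RP
falls in the closest 5% of all pooled distances (one global angstrom
threshold for all RPs; ~27.4 A on the human 80S structure).  Per-RP sets are
ordered closest-first and capped (default 360 positions, i.e. 5% of the human
rRNA length).  For the enrichment null, each contact set gets B background
sets, each an exact circular translation of the set along the concatenated
rRNA axis by multiples of a species-specific shift (~1% of total length;
human 71 nt, mouse 67 nt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .reference import RRNAReference
from .structure import ProximityMatrix

__all__ = [
    "ContactSetCollection",
    "compute_threshold",
    "build_contact_sets",
    "build_background_sets",
    "default_shift",
    "build_collection",
    "SPECIES_SHIFTS",
]

# Printed species presets; they take precedence over round(0.01 * L), which
# is only approximate for the real references.
SPECIES_SHIFTS: dict[str, int] = {"human": 71, "mouse": 67}


def compute_threshold(
    pm: ProximityMatrix, percentile: float = 0.05, per_rp: bool = False
) -> float | np.ndarray:
    """Contact threshold: the ``percentile`` quantile of distances (type-7).

    By default all finite entries are pooled across RPs and positions and a
    single angstrom threshold is returned (one tau for all RPs).  With
    ``per_rp`` each RP gets its own row-wise quantile (sensitivity-analysis
    mode; returns an array aligned with ``pm.rp_ids``).
    """
    if not 0 < percentile <= 1:
        raise ValueError(f"percentile must be in (0, 1], got {percentile}")
    values = pm.present_values()
    if values.size == 0:
        raise ValueError("proximity matrix has no present distances")
    if per_rp:
        return np.nanquantile(pm.distances, percentile, axis=1)
    return float(np.quantile(values, percentile))


def build_contact_sets(
    pm: ProximityMatrix, tau: float | np.ndarray, K: int = 360
) -> dict[str, np.ndarray]:
    """Per-RP contact positions: distance <= tau, closest first, capped at K.

    ``tau`` may be a single pooled threshold or a per-RP array (see
    :func:`compute_threshold`).  Ties in distance break by ascending
    concatenated position, so the result is deterministic.
    """
    taus = np.broadcast_to(np.asarray(tau, dtype=float), (pm.n_rp,))
    if np.any(taus <= 0):
        raise ValueError(f"threshold tau must be positive, got {tau}")
    if K < 1:
        raise ValueError(f"set-size cap K must be >= 1, got {K}")
    sets: dict[str, np.ndarray] = {}
    for i, rp in enumerate(pm.rp_ids):
        row = pm.distances[i]
        hits = np.flatnonzero(np.isfinite(row) & (row <= taus[i]))
        order = np.lexsort((hits, row[hits]))  # distance asc, position asc
        sets[rp] = hits[order][:K]
    return sets


def build_background_sets(
    contact_set: np.ndarray, L: int, s: int, B: int = 100
) -> list[np.ndarray]:
    """B circular translations of ``contact_set``: set + b*s (mod L), b=1..B."""
    if s == 0:
        raise ValueError("background shift s must be nonzero")
    if s < 0:
        raise ValueError(f"background shift s must be positive, got {s}")
    if B * s >= L:
        warnings.warn(
            f"B*s = {B * s} >= L = {L}: background shifts wrap past a full "
            "turn; some background sets may coincide with the contact set",
            stacklevel=2,
        )
    contact_set = np.asarray(contact_set, dtype=np.int64)
    out = []
    for b in range(1, B + 1):
        if (b * s) % L == 0:
            warnings.warn(
                f"shift {b}*{s} is a multiple of L={L}: background {b} equals "
                "the contact set",
                stacklevel=2,
            )
        out.append((contact_set + b * s) % L)
    return out


def default_shift(ref: RRNAReference) -> int:
    """Background shift: species preset if known, else round(0.01 * L)."""
    if ref.species in SPECIES_SHIFTS:
        return SPECIES_SHIFTS[ref.species]
    return int(round(0.01 * ref.total_length))


@dataclass
class ContactSetCollection:
    """Contact sets plus their circular-shift backgrounds for every RP."""

    reference: RRNAReference
    threshold_tau: float
    max_set_size: int
    shift_s: int
    n_backgrounds: int
    sets: dict[str, np.ndarray]
    distances: dict[str, np.ndarray] = field(default_factory=dict)
    backgrounds: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rp, pos in self.sets.items():
            if len(pos) > self.max_set_size:
                raise ValueError(f"contact set of {rp} exceeds cap {self.max_set_size}")
        for rp, bgs in self.backgrounds.items():
            if any(len(bg) != len(self.sets[rp]) for bg in bgs):
                raise ValueError(f"background cardinality mismatch for {rp}")

    @property
    def rp_ids(self) -> list[str]:
        return list(self.sets)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for rp, positions in self.sets.items():
            dists = self.distances.get(rp)
            for rank, p in enumerate(positions, start=1):
                rid, pos1 = self.reference.from_concatenated(int(p))
                rows.append(
                    {
                        "rp_id": rp,
                        "rank": rank,
                        "rrna_id": rid,
                        "pos_1based": pos1,
                        "distance_A": float(dists[rank - 1]) if dists is not None else np.nan,
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.3f")

    def to_bed(self, path: str | Path) -> None:
        """BED-like export: per-rRNA 0-based half-open single-base intervals."""
        rows = []
        for rp, positions in self.sets.items():
            for p in positions:
                rid, pos1 = self.reference.from_concatenated(int(p))
                rows.append((rid, pos1 - 1, pos1, rp))
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(
            path, sep="\t", index=False, header=False
        )


def build_collection(
    pm: ProximityMatrix,
    percentile: float = 0.05,
    K: int = 360,
    B: int = 100,
    shift: int | None = None,
) -> ContactSetCollection:
    """Threshold, contact sets and backgrounds from a proximity matrix."""
    tau = compute_threshold(pm, percentile)
    sets = build_contact_sets(pm, tau, K)
    s = shift if shift is not None else default_shift(pm.reference)
    L = pm.reference.total_length
    distances = {}
    backgrounds = {}
    for i, rp in enumerate(pm.rp_ids):
        distances[rp] = pm.distances[i][sets[rp]]
        backgrounds[rp] = build_background_sets(sets[rp], L, s, B)
    return ContactSetCollection(
        reference=pm.reference,
        threshold_tau=tau,
        max_set_size=K,
        shift_s=s,
        n_backgrounds=B,
        sets=sets,
        distances=distances,
        backgrounds=backgrounds,
    )
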