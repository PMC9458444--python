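"""Ribosome structure parsing and the RP-rRNA proximity matrix.

From an mmCIF model of the ribosome (e.g. PDB 4V6X for the human 80S), every
rRNA residue is reduced to its N1 atom and every ribosomal-protein (RP)
residue to its alpha carbon.  The proximity matrix stores, for each RP and
each rRNA position of the concatenated reference, the minimum Euclidean
distance (in angstrom) from the residue's N1 atom to any alpha carbon of that
RP.  Structurally unresolved residues (no N1 atom, or absent from the model)
are missing (NaN) for every RP.

A matrix built for one species can be transferred to another through a
residue alignment map: aligned residues copy their distance, target-only
residues (insertions) are linearly interpolated between the nearest aligned
flanks within the same rRNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .reference import ResidueAlignmentMap, RRNAReference

__all__ = [
    "StructureModel",
    "ProximityMatrix",
    "parse_structure",
    "build_proximity_matrix",
    "transfer_matrix",
    "StructureFormatError",
    "ChainConfigurationError",
    "SequenceMismatchError",
]


class StructureFormatError(ValueError):
    """The structure file could not be parsed."""


class ChainConfigurationError(ValueError):
    """A configured chain is absent from the model."""


class SequenceMismatchError(ValueError):
    """Structure chain sequence disagrees with the FASTA reference."""


_RNA_ONE_LETTER = {
    "A": "A", "C": "C", "G": "G", "U": "T", "T": "T",
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "T",
}


@dataclass
class StructureModel:
    """Residue-level reference points extracted from one mmCIF model.

    ``rna_points[rrna_id]`` maps 1-based residue numbers to N1 coordinates and
    one-letter codes; ``rp_coords[chain]`` is the (n, 3) array of alpha-carbon
    coordinates of one candidate RP chain.
    """

    rna_points: dict[str, dict[int, np.ndarray]]
    rna_letters: dict[str, dict[int, str]]
    rp_coords: dict[str, np.ndarray]

    @property
    def rp_ids(self) -> list[str]:
        return list(self.rp_coords)


def parse_structure(
    cif_path: str | Path,
    rrna_chain_map: Mapping[str, str],
    rp_exclude: Sequence[str] = (),
) -> StructureModel:
    """Extract N1/CA reference points from an mmCIF file.

    Parameters
    ----------
    rrna_chain_map:
        rrna_id -> chain name.  Chains listed here are treated as rRNA; every
        other polypeptide chain (at least one amino-acid residue with a CA
        atom) is a candidate RP unless listed in ``rp_exclude``.
    rp_exclude:
        Deny-list of chain names that are polypeptides but not ribosomal
        proteins (e.g. bound factors).
    """
    try:
        st = gemmi.read_structure(str(cif_path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {cif_path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"no models in {cif_path}")
    st.setup_entities()
    model = st[0]
    chain_names = {ch.name for ch in model}
    missing = [c for c in rrna_chain_map.values() if c not in chain_names]
    if missing:
        raise ChainConfigurationError(
            f"rRNA chain(s) {missing} not found in {cif_path}; "
            f"available chains: {sorted(chain_names)}"
        )

    rna_chain_to_id = {chain: rid for rid, chain in rrna_chain_map.items()}
    rna_points: dict[str, dict[int, np.ndarray]] = {
        rid: {} for rid in rrna_chain_map
    }
    rna_letters: dict[str, dict[int, str]] = {rid: {} for rid in rrna_chain_map}
    rp_coords: dict[str, np.ndarray] = {}
    excluded = set(rp_exclude)

    for chain in model:
        if chain.name in rna_chain_to_id:
            rid = rna_chain_to_id[chain.name]
            for res in chain:
                letter = _RNA_ONE_LETTER.get(res.name.strip().upper())
                if letter is None:
                    continue  # ligand/ion on the rRNA chain
                atom = res.find_atom("N1", "*")
                if atom is None:
                    continue  # unresolved base: stays missing, not an error
                pos = res.seqid.num
                rna_points[rid][pos] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z]
                )
                rna_letters[rid][pos] = letter
        else:
            cas: list[list[float]] = []
            n_aa = 0
            for res in chain:
                info = gemmi.find_tabulated_residue(res.name)
                if info is None or not info.is_amino_acid():
                    continue
                n_aa += 1
                atom = res.find_atom("CA", "*")
                if atom is not None and atom.element != gemmi.Element("Ca"):
                    cas.append([atom.pos.x, atom.pos.y, atom.pos.z])
            if n_aa and cas and chain.name not in excluded:
                rp_coords[chain.name] = np.asarray(cas, dtype=float)
    return StructureModel(
        rna_points=rna_points, rna_letters=rna_letters, rp_coords=rp_coords
    )


@dataclass
class ProximityMatrix:
    """Minimum RP-rRNA distances on the concatenated coordinate axis.

    Rows are RPs, columns are concatenated rRNA positions; values in angstrom,
    NaN where the residue is structurally unresolved.
    """

    rp_ids: list[str]
    distances: np.ndarray  # (n_rp, L) float, NaN = missing
    reference: RRNAReference

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.shape != (len(self.rp_ids), self.reference.total_length):
            raise ValueError(
                f"distance matrix shape {self.distances.shape} does not match "
                f"{len(self.rp_ids)} RPs x L={self.reference.total_length}"
            )
        present = self.distances[np.isfinite(self.distances)]
        if present.size and present.min() < 0:
            raise ValueError("distances must be non-negative")

    @property
    def n_rp(self) -> int:
        return len(self.rp_ids)

    def present_values(self) -> np.ndarray:
        """All finite entries, pooled across RPs and positions."""
        return self.distances[np.isfinite(self.distances)]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.distances, index=self.rp_ids, columns=self.reference.labels()
        )
        df.index.name = "rp_id"
        df.to_csv(path, sep="\t", float_format="%.3f", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path, reference: RRNAReference) -> "ProximityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        expected = reference.labels()
        if list(df.columns) != expected:
            raise ValueError(
                f"proximity matrix columns in {path} do not match the reference "
                f"({len(df.columns)} columns vs L={len(expected)})"
            )
        return cls(
            rp_ids=[str(i) for i in df.index],
            distances=df.to_numpy(dtype=float),
            reference=reference,
        )


def build_proximity_matrix(
    model: StructureModel,
    ref: RRNAReference,
    max_mismatch_frac: float = 0.01,
) -> ProximityMatrix:
    """Compute min distances from every rRNA residue N1 to every RP's CAs.

    The structure chain sequence (over resolved residues) must match the FASTA
    reference at >= ``1 - max_mismatch_frac`` identity; mismatching positions
    are reported in the raised error rather than silently used.
    """
    L = ref.total_length
    n_rp = len(model.rp_coords)
    dist = np.full((n_rp, L), np.nan)

    mismatches: list[str] = []
    n_checked = 0
    cols: list[int] = []
    coords: list[np.ndarray] = []
    for rid in ref.ids:
        seq = ref.sequence(rid)
        points = model.rna_points.get(rid, {})
        letters = model.rna_letters.get(rid, {})
        for pos, xyz in points.items():
            if not 1 <= pos <= len(seq):
                mismatches.append(f"{rid}:{pos} outside reference length {len(seq)}")
                continue
            n_checked += 1
            if letters[pos] != seq[pos - 1]:
                mismatches.append(
                    f"{rid}:{pos} structure={letters[pos]} fasta={seq[pos - 1]}"
                )
                continue
            cols.append(ref.to_concatenated(rid, pos))
            coords.append(xyz)
    if n_checked and len(mismatches) > max_mismatch_frac * n_checked:
        shown = "; ".join(mismatches[:10])
        raise SequenceMismatchError(
            f"{len(mismatches)}/{n_checked} resolved residues disagree with the "
            f"reference (tolerance {max_mismatch_frac:.0%}): {shown}"
        )
    if coords:
        xyz = np.vstack(coords)
        col_idx = np.asarray(cols, dtype=np.int64)
        for i, rp in enumerate(model.rp_coords):
            tree = cKDTree(model.rp_coords[rp])
            d, _ = tree.query(xyz, k=1)
            dist[i, col_idx] = d
    return ProximityMatrix(
        rp_ids=list(model.rp_coords), distances=dist, reference=ref
    )


def transfer_matrix(
    source_pm: ProximityMatrix,
    amap: ResidueAlignmentMap,
    target_ref: RRNAReference,
) -> ProximityMatrix:
    """Transfer a proximity matrix onto a second species' reference.

    Aligned target residues copy the source distance directly.  Unaligned
    target residues (insertions) between two aligned flanks get per-RP
    linearly interpolated distances; beyond the outermost aligned residue of
    an rRNA they copy the nearest aligned value.  A NaN flank propagates the
    value of the single resolved side; two NaN flanks stay NaN.
    """
    if amap.source_length != source_pm.reference.total_length:
        raise ValueError("alignment map does not index the source reference")
    if amap.target_length != target_ref.total_length:
        raise ValueError("alignment map does not index the target reference")
    n_rp = source_pm.n_rp
    out = np.full((n_rp, target_ref.total_length), np.nan)
    src = source_pm.distances
    pairs = amap.pairs
    if pairs.size:
        out[:, pairs[:, 1]] = src[:, pairs[:, 0]]

    for _, start, stop in target_ref.record_bounds():
        in_rec = (pairs[:, 1] >= start) & (pairs[:, 1] < stop) if pairs.size else None
        t_aligned = pairs[in_rec, 1] if pairs.size else np.empty(0, np.int64)
        if t_aligned.size == 0:
            continue  # whole record unaligned: stays missing
        un = amap.unaligned_target
        un_rec = un[(un >= start) & (un < stop)]
        if un_rec.size == 0:
            continue
        right_i = np.searchsorted(t_aligned, un_rec)
        for p, ri in zip(un_rec, right_i):
            left = t_aligned[ri - 1] if ri > 0 else None
            right = t_aligned[ri] if ri < t_aligned.size else None
            if left is None:
                out[:, p] = out[:, right]
            elif right is None:
                out[:, p] = out[:, left]
            else:
                frac = (p - left) / (right - left)
                lv, rv = out[:, left], out[:, right]
                both = np.isfinite(lv) & np.isfinite(rv)
                val = np.where(both, lv + frac * (rv - lv), np.nan)
                only_l = np.isfinite(lv) & ~np.isfinite(rv)
                only_r = ~np.isfinite(lv) & np.isfinite(rv)
                val = np.where(only_l, lv, val)
                val = np.where(only_r, rv, val)
                out[:, p] = val
    return ProximityMatrix(
        rp_ids=list(source_pm.rp_ids), distances=out, reference=target_ref
    )
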