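"""Synthetic fixtures: toy ribosome structures and NB-simulated count data.

The generator emulates the protection-change model behind the pipeline: a
difference in the incorporation of one RP alters RNase accessibility, hence
Ribo-seq rRNA fragment abundance, specifically at rRNA positions in that
RP's structural vicinity.  Counts are negative binomial around a log-normal
positional baseline; the condition effect is a multiplicative (log-scale)
shift confined to a random subset of the target RP's contact points, because
in real data only hotspots within an RP's vicinity change, not the whole
neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import ContactSetCollection
from .quant import PositionalCountMatrix, write_bedgraph
from .reference import RRNAReference

__all__ = ["SimulationSpec", "make_toy_structure", "simulate_counts", "write_bundle"]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one simulated two-group experiment."""

    n_samples_per_group: int = 3
    dispersion: float = 0.1
    depth: float = 50.0  # mean fragment coverage per position
    target_rp: str | None = None
    effect_log2fc: float = 1.5
    effect_fraction: float = 0.6
    baseline_sigma: float = 1.0  # sd of the log-normal positional profile
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.effect_fraction <= 1:
            raise ValueError("effect_fraction must be in [0, 1]")


_CIF_HEADER = """data_toy_ribosome
#
_entry.id toy_ribosome
#
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
"""


def make_toy_structure(
    n_rrna_residues: int,
    n_rps: int,
    seed: int,
    cif_path: str | Path,
    fasta_path: str | Path,
    rrna_id: str = "rRNA_toy",
    atoms_per_rp: int = 8,
) -> dict[str, str]:
    """Write a minimal valid mmCIF + FASTA for a toy single-rRNA ribosome.

    The rRNA chain carries one N1 atom per residue along a 3D helix; each of
    the ``n_rps`` protein chains carries CA atoms clustered ~10 A outside a
    distinct residue range, so each RP's nearest residues are the ones it was
    placed near.  Output is byte-deterministic under the seed.

    Returns the rRNA chain map ({rrna_id: chain_name}) for the parser.
    """
    if n_rrna_residues < 3:
        raise ValueError("need at least 3 rRNA residues")
    if n_rps < 1:
        raise ValueError("need at least 1 RP")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(_BASES), size=n_rrna_residues))
    # helix: successive N1 atoms ~18 A apart, radius 30 A
    t = np.arange(n_rrna_residues) * 0.6
    rna_xyz = np.column_stack([30 * np.cos(t), 30 * np.sin(t), 3.0 * np.arange(n_rrna_residues)])

    lines: list[str] = []
    atom_id = 1
    comp_of = {"A": "A", "C": "C", "G": "G", "T": "U"}  # RNA residue names
    for i, base in enumerate(seq):
        x, y, z = rna_xyz[i]
        lines.append(
            f"ATOM {atom_id} N N1 . {comp_of[base]} A 1 {i + 1} ? "
            f"{x:.3f} {y:.3f} {z:.3f} 1.00 0.00 {i + 1} A 1"
        )
        atom_id += 1

    chain_names = [f"P{j}" for j in range(1, n_rps + 1)]
    centers = ((np.arange(n_rps) + 0.5) * n_rrna_residues / n_rps).astype(int)
    for j, chain in enumerate(chain_names):
        c = rna_xyz[centers[j]]
        outward = c[:2] / np.linalg.norm(c[:2])
        anchor = c + np.array([outward[0] * 10.0, outward[1] * 10.0, 0.0])
        offsets = rng.normal(scale=4.0, size=(atoms_per_rp, 3))
        for a in range(atoms_per_rp):
            x, y, z = anchor + offsets[a]
            lines.append(
                f"ATOM {atom_id} C CA . GLY {chain} {j + 2} {a + 1} ? "
                f"{x:.3f} {y:.3f} {z:.3f} 1.00 0.00 {a + 1} {chain} 1"
            )
            atom_id += 1

    Path(cif_path).write_text(_CIF_HEADER + "\n".join(lines) + "\n#\n")
    Path(fasta_path).write_text(f">{rrna_id}\n{seq}\n")
    return {rrna_id: "A"}


def simulate_counts(
    ref: RRNAReference,
    collection: ContactSetCollection | None,
    spec: SimulationSpec,
) -> tuple[PositionalCountMatrix, pd.DataFrame]:
    """Simulate a two-group positional count matrix with an RP-localized effect.

    Returns the matrix plus a truth table of affected positions (empty for a
    null simulation).  Group B means are the group A means times
    ``2**effect_log2fc`` at a seeded random subset (``effect_fraction``) of
    the target RP's contact positions.
    """
    rng = np.random.default_rng(spec.seed)
    L = ref.total_length
    mu_log = np.log(spec.depth) - 0.5 * spec.baseline_sigma**2
    base_mean = np.exp(rng.normal(mu_log, spec.baseline_sigma, size=L))

    affected = np.empty(0, dtype=np.int64)
    if spec.target_rp is not None:
        if collection is None or spec.target_rp not in collection.sets:
            raise KeyError(f"target RP {spec.target_rp!r} not in the contact sets")
        contact = collection.sets[spec.target_rp]
        n_aff = int(round(spec.effect_fraction * len(contact)))
        affected = np.sort(rng.choice(contact, size=n_aff, replace=False))

    mean_b = base_mean.copy()
    mean_b[affected] *= 2.0**spec.effect_log2fc

    n = spec.n_samples_per_group
    means = [base_mean] * n + [mean_b] * n

    def draw(mu: np.ndarray) -> np.ndarray:
        if spec.dispersion == 0:
            return rng.poisson(mu)
        size = 1.0 / spec.dispersion
        return rng.negative_binomial(size, size / (size + mu))

    counts = np.vstack([draw(mu) for mu in means])
    sample_ids = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    conditions = ["A"] * n + ["B"] * n
    matrix = PositionalCountMatrix(
        sample_ids=sample_ids,
        conditions=conditions,
        counts=counts,
        reference=ref,
        single_replicate=(n < 2),
    )
    rows = []
    for p in affected:
        rid, pos1 = ref.from_concatenated(int(p))
        rows.append(
            dict(rrna_id=rid, pos_1based=pos1, concat_index=int(p),
                 true_log2fc=spec.effect_log2fc, target_rp=spec.target_rp)
        )
    truth = pd.DataFrame(
        rows, columns=["rrna_id", "pos_1based", "concat_index", "true_log2fc", "target_rp"]
    )
    return matrix, truth


def write_bundle(
    out_dir: str | Path,
    matrix: PositionalCountMatrix,
    truth: pd.DataFrame,
    ref: RRNAReference,
) -> dict[str, Path]:
    """Write per-sample bedGraphs, the sample sheet and the truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    sheet_rows = []
    for i, sid in enumerate(matrix.sample_ids):
        bg = out / f"{sid}.bedGraph"
        write_bedgraph(matrix.counts[i], ref, bg)
        sheet_rows.append(dict(sample_id=sid, path=str(bg), condition=matrix.conditions[i]))
        paths[sid] = bg
    sheet = out / "samples.tsv"
    pd.DataFrame(sheet_rows).to_csv(sheet, sep="\t", index=False)
    paths["sample_sheet"] = sheet
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
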