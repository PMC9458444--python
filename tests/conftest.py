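"""Shared fixtures: toy references, toy structures, SAM writing helpers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

import ribohet as rh


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """Deterministic toy ribosome: 640-nt rRNA, 6 RPs, proximity + contact sets.

    640 residues keep B*s = 100*6 < L so background shifts never complete a
    full circular turn.
    """
    d = tmp_path_factory.mktemp("toy_structure")
    cif, fasta = d / "toy.cif", d / "toy.fasta"
    chain_map = rh.make_toy_structure(640, 6, seed=11, cif_path=cif, fasta_path=fasta)
    ref = rh.load_reference(fasta)
    model = rh.parse_structure(cif, chain_map)
    pm = rh.build_proximity_matrix(model, ref)
    coll = rh.build_collection(pm)
    return {
        "dir": d,
        "cif": cif,
        "fasta": fasta,
        "chain_map": chain_map,
        "ref": ref,
        "model": model,
        "pm": pm,
        "collection": coll,
    }


@pytest.fixture()
def small_ref():
    """Two-rRNA reference with simple lengths (offsets 0 and 100)."""
    rng = np.random.default_rng(7)
    s1 = "".join(rng.choice(list("ACGT"), size=100))
    s2 = "".join(rng.choice(list("ACGT"), size=50))
    return rh.RRNAReference(records=(("18S", s1), ("5S", s2)))


def make_reference(*seqs: str, ids: list[str] | None = None) -> rh.RRNAReference:
    ids = ids or [f"r{i}" for i in range(1, len(seqs) + 1)]
    return rh.RRNAReference(records=tuple(zip(ids, seqs)))


def write_sam(path: Path, ref: rh.RRNAReference, records: list[str]) -> Path:
    """Write a SAM with @SQ headers matching ``ref`` plus the given records."""
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for rid, seq in ref.records:
        lines.append(f"@SQ\tSN:{rid}\tLN:{len(seq)}")
    lines.extend(records)
    path.write_text("\n".join(lines) + "\n")
    return path


def sam_record(
    qname: str,
    rid: str,
    pos_1based: int,
    cigar: str,
    seq: str,
    flag: int = 0,
) -> str:
    return f"{qname}\t{flag}\t{rid}\t{pos_1based}\t60\t{cigar}\t*\t0\t0\t{seq}\t*"
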