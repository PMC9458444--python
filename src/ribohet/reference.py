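"""rRNA reference sequences and the concatenated coordinate system.

The pipeline works on a single coordinate axis obtained by concatenating the
species' rRNAs (28S, 18S, 5.8S, 5S by default) in a fixed, configurable order.
Within each rRNA, positions are 1-based; the concatenated axis is 0-based and
internal.  The concatenated axis is treated as circular by the background-set
machinery, which is why a single well-defined total length matters.

Cross-species transfer of structural information relies on per-rRNA global
pairwise alignments (28S to 28S, 18S to 18S, ...); the resulting residue
correspondence map is consumed by :func:`ribohet.structure.transfer_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, SeqIO

__all__ = [
    "RRNAReference",
    "ResidueAlignmentMap",
    "load_reference",
    "align_references",
    "ReferenceError",
    "CoordinateError",
]


class ReferenceError(ValueError):
    """A requested rRNA id is missing, duplicated, or malformed."""


class CoordinateError(ValueError):
    """A position is outside the valid 1-based range of its rRNA."""


_IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class RRNAReference:
    """Ordered collection of rRNA sequences with a concatenated coordinate map.

    Sequences are stored in the DNA alphabet (U normalized to T at load time).
    """

    records: tuple[tuple[str, str], ...]
    species: str | None = None
    offsets: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        offsets: dict[str, int] = {}
        at = 0
        for rrna_id, seq in self.records:
            if rrna_id in seen:
                raise ReferenceError(f"duplicate rRNA id {rrna_id!r}")
            if not seq:
                raise ReferenceError(f"empty sequence for rRNA id {rrna_id!r}")
            bad = set(seq) - _IUPAC
            if bad:
                raise ReferenceError(
                    f"non-IUPAC characters {sorted(bad)} in rRNA {rrna_id!r}"
                )
            seen.add(rrna_id)
            offsets[rrna_id] = at
            at += len(seq)
        object.__setattr__(self, "offsets", offsets)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.records)

    def sequence(self, rrna_id: str) -> str:
        for rid, seq in self.records:
            if rid == rrna_id:
                return seq
        raise ReferenceError(f"unknown rRNA id {rrna_id!r}")

    def length(self, rrna_id: str) -> int:
        return len(self.sequence(rrna_id))

    def to_concatenated(self, rrna_id: str, pos_1based: int) -> int:
        """Map (rrna_id, 1-based position) to the 0-based concatenated index."""
        n = self.length(rrna_id)
        if not 1 <= pos_1based <= n:
            raise CoordinateError(
                f"position {pos_1based} outside 1..{n} for rRNA {rrna_id!r}"
            )
        return self.offsets[rrna_id] + pos_1based - 1

    def from_concatenated(self, index: int) -> tuple[str, int]:
        """Inverse of :meth:`to_concatenated`."""
        if not 0 <= index < self.total_length:
            raise CoordinateError(
                f"concatenated index {index} outside 0..{self.total_length - 1}"
            )
        for rid, seq in self.records:
            off = self.offsets[rid]
            if off <= index < off + len(seq):
                return rid, index - off + 1
        raise AssertionError("unreachable")  # pragma: no cover

    def record_bounds(self) -> list[tuple[str, int, int]]:
        """Half-open concatenated bounds [start, stop) per record, in order."""
        return [
            (rid, self.offsets[rid], self.offsets[rid] + len(seq))
            for rid, seq in self.records
        ]

    def labels(self) -> list[str]:
        """``rrna_id:pos`` labels for every concatenated index, in order."""
        out: list[str] = []
        for rid, seq in self.records:
            out.extend(f"{rid}:{p}" for p in range(1, len(seq) + 1))
        return out


def load_reference(
    fasta_path: str | Path,
    order: Sequence[str] | None = None,
    species: str | None = None,
) -> RRNAReference:
    """Load rRNA sequences from a multi-FASTA into an :class:`RRNAReference`.

    Parameters
    ----------
    fasta_path:
        Multi-record FASTA.  Record ids are matched on the first whitespace
        token of the header.
    order:
        Concatenation order.  Defaults to file order.  Every requested id must
        be present in the file.
    """
    by_id: dict[str, str] = {}
    file_order: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in by_id:
            raise ReferenceError(f"duplicate FASTA record {rec.id!r} in {fasta_path}")
        by_id[rec.id] = str(rec.seq).upper().replace("U", "T")
        file_order.append(rec.id)
    if not by_id:
        raise ReferenceError(f"no FASTA records found in {fasta_path}")
    wanted = list(order) if order is not None else file_order
    missing = [rid for rid in wanted if rid not in by_id]
    if missing:
        raise ReferenceError(
            f"rRNA id(s) {missing} requested but absent from {fasta_path}"
        )
    return RRNAReference(
        records=tuple((rid, by_id[rid]) for rid in wanted), species=species
    )


@dataclass(frozen=True)
class ResidueAlignmentMap:
    """Residue correspondence between two references, in concatenated coordinates.

    ``pairs`` holds aligned (source_index, target_index) columns, strictly
    increasing in both coordinates; ``unaligned_target`` holds target indices
    with no source partner (insertions in the target species).  Together they
    account for every target position exactly once.
    """

    pairs: np.ndarray  # (n, 2) int
    unaligned_target: np.ndarray  # (m,) int
    source_length: int
    target_length: int

    def __post_init__(self) -> None:
        p = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        u = np.asarray(self.unaligned_target, dtype=np.int64).ravel()
        object.__setattr__(self, "pairs", p)
        object.__setattr__(self, "unaligned_target", u)
        if p.size and (np.any(np.diff(p[:, 0]) <= 0) or np.any(np.diff(p[:, 1]) <= 0)):
            raise ValueError("alignment pairs must be strictly increasing (no crossing)")
        covered = np.concatenate([p[:, 1], u]) if p.size or u.size else np.empty(0, int)
        if len(np.unique(covered)) != self.target_length or (
            covered.size and (covered.min() < 0 or covered.max() >= self.target_length)
        ):
            raise ValueError("every target position must appear exactly once")

    def is_identity(self) -> bool:
        return (
            self.unaligned_target.size == 0
            and self.pairs.shape[0] == self.target_length == self.source_length
            and bool(np.all(self.pairs[:, 0] == self.pairs[:, 1]))
        )


def _make_aligner() -> Align.PairwiseAligner:
    # Standard nucleotide scoring; the contract is the correspondence map,
    # not a particular optimal alignment.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def align_references(
    source: RRNAReference, target: RRNAReference
) -> ResidueAlignmentMap:
    """Globally align each rRNA of ``source`` to its counterpart in ``target``.

    Records are matched by order (28S to 28S, 18S to 18S, ...); the two
    references must have the same number of records.
    """
    if len(source.records) != len(target.records):
        raise ValueError(
            "source and target references must have the same number of rRNAs "
            f"({len(source.records)} vs {len(target.records)})"
        )
    aligner = _make_aligner()
    all_pairs: list[np.ndarray] = []
    all_unaligned: list[np.ndarray] = []
    for (sid, sseq), (tid, tseq) in zip(source.records, target.records):
        aln = aligner.align(sseq, tseq)[0]
        s_blocks, t_blocks = aln.aligned
        soff = source.offsets[sid]
        toff = target.offsets[tid]
        aligned_t: list[np.ndarray] = []
        for (ss, se), (ts, te) in zip(s_blocks, t_blocks):
            src_idx = np.arange(ss, se) + soff
            tgt_idx = np.arange(ts, te) + toff
            all_pairs.append(np.column_stack([src_idx, tgt_idx]))
            aligned_t.append(np.arange(ts, te))
        covered = (
            np.concatenate(aligned_t) if aligned_t else np.empty(0, dtype=np.int64)
        )
        un = np.setdiff1d(np.arange(len(tseq)), covered) + toff
        all_unaligned.append(un)
    pairs = (
        np.concatenate(all_pairs) if all_pairs else np.empty((0, 2), dtype=np.int64)
    )
    unaligned = (
        np.concatenate(all_unaligned) if all_unaligned else np.empty(0, dtype=np.int64)
    )
    return ResidueAlignmentMap(
        pairs=pairs,
        unaligned_target=np.sort(unaligned),
        source_length=source.total_length,
        target_length=target.total_length,
    )
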