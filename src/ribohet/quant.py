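"""Per-nucleotide rRNA fragment quantification.

Converts rRNA alignments (BAM/SAM) or coverage tracks (bedGraph) into a
samples x concatenated-positions count matrix.  Coverage is full-read
per-base: every reference position covered by an aligned block of a counted
read is incremented (deletions and skips are not counted).  Read filters
default to: primary, mapped, non-QC-fail, sense strand; duplicates are kept
because Ribo-seq fragments are legitimately duplicated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .reference import RRNAReference

__all__ = [
    "PositionalCountMatrix",
    "coverage_from_bam",
    "coverage_from_bedgraph",
    "assemble_matrix",
    "filter_low_counts",
    "write_bedgraph",
    "read_sample_sheet",
]


class CoverageValidationError(ValueError):
    """Alignment or track references do not match the rRNA reference."""


def coverage_from_bam(
    bam_path: str | Path,
    ref: RRNAReference,
    *,
    include_duplicates: bool = True,
    include_antisense: bool = False,
    min_read_length: int | None = None,
    max_read_length: int | None = None,
) -> np.ndarray:
    """Per-position fragment coverage from a BAM/SAM aligned to the rRNAs.

    Reference names and lengths in the header must match the loaded rRNA
    reference.  Counts secondary/supplementary/unmapped/QC-fail reads never;
    duplicates and antisense reads according to the flags; optional fragment
    length window on the query length.
    """
    counts = np.zeros(ref.total_length, dtype=np.int64)
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as bam:
        header_lens = dict(zip(bam.references, bam.lengths))
        for rid in ref.ids:
            if rid not in header_lens:
                raise CoverageValidationError(
                    f"reference {rid!r} absent from {bam_path} header"
                )
            if header_lens[rid] != ref.length(rid):
                raise CoverageValidationError(
                    f"length mismatch for {rid!r}: header {header_lens[rid]} vs "
                    f"reference {ref.length(rid)}"
                )
        for read in bam.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_qcfail
            ):
                continue
            if not include_duplicates and read.is_duplicate:
                continue
            if not include_antisense and read.is_reverse:
                continue
            qlen = read.query_length or read.infer_query_length() or 0
            if min_read_length is not None and qlen < min_read_length:
                continue
            if max_read_length is not None and qlen > max_read_length:
                continue
            rid = read.reference_name
            if rid not in ref.offsets:
                continue  # alignment to a contig outside the rRNA set
            off = ref.offsets[rid]
            for start, end in read.get_blocks():
                counts[off + start : off + end] += 1
    return counts


def coverage_from_bedgraph(
    bg_path: str | Path,
    ref: RRNAReference,
    *,
    strict_integers: bool = True,
) -> np.ndarray:
    """Per-position coverage from a bedGraph (0-based half-open intervals).

    Overlapping intervals are summed.  Values must be non-negative integers
    unless ``strict_integers`` is off, in which case they are rounded.
    """
    counts = np.zeros(ref.total_length, dtype=np.int64)
    try:
        df = pd.read_csv(
            bg_path,
            sep=r"\s+",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return counts
    df = df[~df["chrom"].str.startswith("track")]
    if df.empty:
        return counts
    for rid, chunk in df.groupby("chrom", sort=False):
        if rid not in ref.offsets:
            raise CoverageValidationError(
                f"bedGraph {bg_path} refers to unknown reference {rid!r}"
            )
        start = chunk["start"].to_numpy(dtype=np.int64)
        end = chunk["end"].to_numpy(dtype=np.int64)
        value = chunk["value"].to_numpy(dtype=float)
        n = ref.length(rid)
        if np.any(start < 0) or np.any(end > n) or np.any(start >= end):
            raise CoverageValidationError(
                f"bedGraph {bg_path}: interval outside 0..{n} on {rid!r}"
            )
        if np.any(value < 0):
            raise ValueError(f"bedGraph {bg_path}: negative coverage on {rid!r}")
        if strict_integers and np.any(value != np.round(value)):
            raise ValueError(
                f"bedGraph {bg_path}: non-integer coverage on {rid!r} "
                "(pass strict_integers=False to round)"
            )
        ivalue = np.round(value).astype(np.int64)
        off = ref.offsets[rid]
        # difference-array expansion; overlaps sum
        delta = np.zeros(n + 1, dtype=np.int64)
        np.add.at(delta, start, ivalue)
        np.add.at(delta, end, -ivalue)
        counts[off : off + n] += np.cumsum(delta[:-1])
    return counts


def write_bedgraph(counts: np.ndarray, ref: RRNAReference, path: str | Path) -> None:
    """Write per-position counts as a run-length-merged bedGraph."""
    with open(path, "w") as fh:
        for rid, start, stop in ref.record_bounds():
            vec = counts[start:stop]
            if not vec.any():
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            edges = np.concatenate([[0], change, [len(vec)]])
            for a, b in zip(edges[:-1], edges[1:]):
                v = int(vec[a])
                if v:
                    fh.write(f"{rid}\t{a}\t{b}\t{v}\n")


@dataclass
class PositionalCountMatrix:
    """Samples x concatenated rRNA positions, raw fragment coverage."""

    sample_ids: list[str]
    conditions: list[str]
    counts: np.ndarray  # (n_samples, L) int
    reference: RRNAReference
    retained: np.ndarray = field(default=None)  # bool (L,)
    single_replicate: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.sample_ids),
            self.reference.total_length,
        ):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x L={self.reference.total_length}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.retained is None:
            self.retained = np.ones(self.reference.total_length, dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)

    @property
    def condition_levels(self) -> list[str]:
        """Condition levels in lexicographic order (A-vs-B orientation is
        deterministic and label-symmetric: swapping labels flips the sign of
        every log fold change)."""
        return sorted(set(self.conditions))

    def condition_indicator(self) -> np.ndarray:
        """0/1 vector over samples: 1 for the second condition level."""
        levels = self.condition_levels
        return np.asarray([levels.index(c) for c in self.conditions], dtype=float)

    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.retained)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.counts.T, index=self.reference.labels(), columns=self.sample_ids
        )
        df.insert(0, "retained", self.retained.astype(int))
        df.index.name = "position"
        df.to_csv(path, sep="\t")


def read_count_matrix(
    path: str | Path, ref: RRNAReference, design: pd.DataFrame
) -> PositionalCountMatrix:
    """Read back a count-matrix TSV written by :meth:`PositionalCountMatrix.to_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != ref.labels():
        raise ValueError(f"count matrix rows in {path} do not match the reference")
    retained = df.pop("retained").to_numpy(dtype=bool)
    sample_ids = list(design["sample_id"])
    missing = [s for s in sample_ids if s not in df.columns]
    if missing:
        raise KeyError(f"sample(s) {missing} absent from count matrix {path}")
    conditions = list(design["condition"])
    n_min = min(conditions.count(c) for c in set(conditions))
    return PositionalCountMatrix(
        sample_ids=sample_ids,
        conditions=conditions,
        counts=df[sample_ids].to_numpy(dtype=np.int64).T,
        reference=ref,
        retained=retained,
        single_replicate=(n_min < 2),
    )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV with columns sample_id, path, condition."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "path", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks column(s) {sorted(missing)}")
    return df


def assemble_matrix(
    per_sample: Mapping[str, np.ndarray],
    design: pd.DataFrame,
    ref: RRNAReference,
) -> PositionalCountMatrix:
    """Stack per-sample coverage vectors following the sample sheet.

    Exactly two condition groups are required.  A group with a single
    replicate triggers a warning and sets the ``single_replicate`` flag so the
    differential stage can fall back to a fixed conservative dispersion.
    """
    sample_ids = list(design["sample_id"])
    missing = [s for s in sample_ids if s not in per_sample]
    if missing:
        raise KeyError(f"sample(s) {missing} in the design have no count vector")
    vectors = []
    for s in sample_ids:
        v = np.asarray(per_sample[s])
        if v.shape != (ref.total_length,):
            raise ValueError(
                f"sample {s!r}: vector length {v.shape} != L={ref.total_length}"
            )
        vectors.append(v)
    conditions = list(design["condition"])
    levels = sorted(set(conditions))
    if len(levels) != 2:
        raise ValueError(f"exactly two conditions required, got {levels}")
    single = False
    for lev in levels:
        n = conditions.count(lev)
        if n < 2:
            single = True
            warnings.warn(
                f"condition {lev!r} has {n} replicate(s); dispersion will fall "
                "back to a fixed conservative value",
                stacklevel=2,
            )
    return PositionalCountMatrix(
        sample_ids=sample_ids,
        conditions=conditions,
        counts=np.vstack(vectors),
        reference=ref,
        single_replicate=single,
    )


def filter_low_counts(
    m: PositionalCountMatrix, min_mean: float = 1.0
) -> PositionalCountMatrix:
    """Retain positions whose mean raw count across all samples >= min_mean."""
    mean = m.counts.mean(axis=0)
    retained = mean >= min_mean
    return replace(m, retained=retained)
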