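"""Barcode observations to per-variant DNA/RNA count tables.

Raw sequencing yields (barcode, promoter-read) pairs during mapping runs and
(barcode, count) pairs per growth sample.  This module applies the read
-support filter, assigns sequenced promoter reads to library variants by
bounded Hamming distance, and aggregates barcode counts into per-variant
count tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .library_design import BarcodeMap, VariantLibrary, encode

logger = logging.getLogger(__name__)

#: Minimum total reads for a promoter/barcode pair to be kept during mapping.
DEFAULT_MIN_READS = 3

#: Maximum Hamming distance for assigning a promoter read to a known variant.
DEFAULT_MAX_MISMATCH = 4

#: Sentinel returned by :func:`assign_variant` for reads beyond the mismatch
#: bound: they are registered as new (synthesis-error) variants.
NEW = "NEW"

#: Sentinel for reads tied between two or more variants.
UNASSIGNED = None


@dataclass
class BarcodeObservation:
    """One barcode seen in a mapping or counting run."""

    barcode: str
    reads: int
    promoter_read: str | None = None

    def __post_init__(self) -> None:
        if self.reads < 0:
            raise ValueError("reads must be >= 0")


@dataclass
class CountTable:
    """Per-variant DNA and RNA counts for one condition/replicate."""

    condition: str
    replicate: int
    variant_ids: list[str]
    dna: np.ndarray
    rna: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dna = np.asarray(self.dna, dtype=np.int64)
        self.rna = np.asarray(self.rna, dtype=np.int64)
        if not (len(self.variant_ids) == self.dna.size == self.rna.size):
            raise ValueError("variant_ids, dna and rna must have equal length")
        if (self.dna < 0).any() or (self.rna < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def total_dna(self) -> int:
        return int(self.dna.sum())

    @property
    def total_rna(self) -> int:
        return int(self.rna.sum())

    def aligned_to(self, variant_ids: Iterable[str]) -> "CountTable":
        """Counts re-indexed to a reference variant order; variants absent
        from this table get zero counts."""
        index = {vid: i for i, vid in enumerate(self.variant_ids)}
        ids = list(variant_ids)
        dna = np.zeros(len(ids), dtype=np.int64)
        rna = np.zeros(len(ids), dtype=np.int64)
        for j, vid in enumerate(ids):
            i = index.get(vid)
            if i is not None:
                dna[j] = self.dna[i]
                rna[j] = self.rna[i]
        return CountTable(self.condition, self.replicate, ids, dna, rna, dict(self.meta))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"variant_id": self.variant_ids, "dna": self.dna, "rna": self.rna}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, condition: str = "", replicate: int = 0
    ) -> "CountTable":
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
        return cls(
            condition=condition,
            replicate=replicate,
            variant_ids=df["variant_id"].tolist(),
            dna=df["dna"].to_numpy(),
            rna=df["rna"].to_numpy(),
        )


def filter_pairs(
    observations: Iterable[BarcodeObservation], min_reads: int = DEFAULT_MIN_READS
) -> list[BarcodeObservation]:
    """Keep only promoter/barcode pairs supported by >= min_reads reads."""
    return [obs for obs in observations if obs.reads >= min_reads]


def assign_variant(
    promoter_read: str,
    library: VariantLibrary,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
):
    """Assign a sequenced promoter read to its nearest library variant.

    Returns the variant index for a unique nearest variant within
    ``max_mismatch`` Hamming distance, :data:`UNASSIGNED` (None) when two or
    more variants tie at the minimum distance, and :data:`NEW` when no
    variant is close enough (the read is a synthesis-error variant and is
    kept as a new library member downstream).
    """
    if len(promoter_read) != library.length:
        raise ValueError(
            f"read length {len(promoter_read)} != library variant length {library.length}"
        )
    read = encode(promoter_read)
    dists = (library.codes != read[None, :]).sum(axis=1)
    best = int(dists.min())
    if best > max_mismatch:
        return NEW
    hits = np.flatnonzero(dists == best)
    if hits.size > 1:
        return UNASSIGNED
    return int(hits[0])


def aggregate_counts(
    dna_barcode_counts: Mapping[str, int],
    rna_barcode_counts: Mapping[str, int],
    bmap: BarcodeMap,
    condition: str = "",
    replicate: int = 0,
) -> CountTable:
    """Sum barcode-level DNA/RNA counts to variant-level counts.

    Barcodes absent from the map are excluded and logged; the numbers of
    unmapped barcodes/reads are recorded in ``meta``.
    """
    sums: dict[str, list[int]] = {}
    unmapped_barcodes = 0
    unmapped_reads = 0
    for source, table in (("dna", dna_barcode_counts), ("rna", rna_barcode_counts)):
        col = 0 if source == "dna" else 1
        for bc, c in table.items():
            entry = bmap.entries.get(bc)
            if entry is None:
                unmapped_barcodes += 1
                unmapped_reads += int(c)
                continue
            vid = entry[0]
            sums.setdefault(vid, [0, 0])[col] += int(c)
    if unmapped_barcodes:
        logger.info(
            "aggregate_counts: excluded %d unmapped barcodes (%d reads)",
            unmapped_barcodes,
            unmapped_reads,
        )
    ids = sorted(sums)
    dna = np.array([sums[v][0] for v in ids], dtype=np.int64)
    rna = np.array([sums[v][1] for v in ids], dtype=np.int64)
    return CountTable(
        condition=condition,
        replicate=replicate,
        variant_ids=ids,
        dna=dna,
        rna=rna,
        meta={
            "unmapped_barcodes": unmapped_barcodes,
            "unmapped_reads": unmapped_reads,
        },
    )


def read_barcode_counts(path: str | Path) -> dict[str, int]:
    """Read a (barcode, count) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    return dict(zip(df["barcode"], df["count"].astype(int)))
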