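"""Design of mutagenized promoter libraries.

A promoter is represented by a fixed window around its transcription start
site (TSS), oriented in the direction of transcription.  The library is a
pool of point-mutant sequences of that window, each optionally tagged with
randomized barcodes and wrapped into a synthesizable oligo construct.

Coordinate convention: the window spans ``up`` bases upstream of the TSS and
``down`` bases downstream, with the TSS base itself counted as the first
downstream base.  Array index ``i`` maps to the promoter-relative label
``i - up``, so label 0 is the TSS base and upstream positions carry negative
labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}

DEFAULT_UP = 115
DEFAULT_DOWN = 45
DEFAULT_RATE = 0.1
DEFAULT_N_VARIANTS = 1500
DEFAULT_BARCODE_LENGTH = 20

#: Restriction sites flanking the promoter insert (SpeI 5', ApaI 3') and the
#: barcode (SbfI 5', SalI 3').
ENZYME_SITES = {
    "SpeI": "ACTAGT",
    "ApaI": "GGGCCC",
    "SbfI": "CCTGCAGG",
    "SalI": "GTCGAC",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - set(DNA_ALPHABET)
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")


_ENCODE_LUT = np.full(128, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int8 array (A=0, C=1, G=2, T=3)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if (codes < 0).any():
        _check_dna(seq)
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(DNA_ALPHABET[c] for c in codes)


@dataclass
class PromoterWindow:
    """A TSS-anchored promoter window in transcription orientation."""

    gene: str
    promoter_name: str
    tss_genomic: int
    strand: str
    sequence: str
    up: int = DEFAULT_UP
    down: int = DEFAULT_DOWN

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        _check_dna(self.sequence, "window sequence")
        if len(self.sequence) != self.up + self.down:
            raise ValueError(
                f"window length {len(self.sequence)} != up+down = {self.up + self.down}"
            )

    def __len__(self) -> int:
        return self.up + self.down

    def label(self, index: int) -> int:
        """Promoter-relative label of array index (label 0 = TSS base)."""
        return index - self.up

    def index(self, label: int) -> int:
        return label + self.up

    def labels(self) -> np.ndarray:
        return np.arange(len(self)) - self.up


@dataclass
class MutagenesisConfig:
    rate: float = DEFAULT_RATE
    n_variants: int = DEFAULT_N_VARIANTS
    include_wildtype: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"mutation rate must be in [0, 1], got {self.rate}")
        if self.n_variants < 1:
            raise ValueError(f"n_variants must be >= 1, got {self.n_variants}")


@dataclass
class VariantLibrary:
    """Ordered pool of point-mutant sequences of one promoter window.

    ``codes`` is a (V, L) int8 matrix of encoded variants; ``masks`` the
    matching boolean matrix of mutated positions.  If the wild type is
    included it is variant 0 with an all-false mask.
    """

    promoter: PromoterWindow
    codes: np.ndarray
    masks: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.codes.shape != self.masks.shape:
            raise ValueError("codes and masks shapes differ")
        if self.codes.shape[1] != len(self.promoter):
            raise ValueError("variant length differs from promoter window length")
        wt = encode(self.promoter.sequence)
        if not np.array_equal(self.masks, self.codes != wt[None, :]):
            raise ValueError("masks inconsistent with variant/wild-type differences")

    @property
    def n_variants(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def variant(self, v: int) -> str:
        return decode(self.codes[v])

    @property
    def variants(self) -> list[str]:
        return [decode(row) for row in self.codes]

    def variant_ids(self) -> list[str]:
        name = self.promoter.promoter_name
        return [f"{name}__v{k}" for k in range(self.n_variants)]


@dataclass
class OligoConstruct:
    variant_id: str
    full_sequence: str
    flags: list[str] = field(default_factory=list)


@dataclass
class BarcodeMap:
    """Mapping of randomized barcodes to variant ids with read support."""

    entries: dict[str, tuple[str, int]]
    barcode_length: int = DEFAULT_BARCODE_LENGTH

    def __post_init__(self) -> None:
        for bc, (_, support) in self.entries.items():
            if len(bc) != self.barcode_length:
                raise ValueError(f"barcode {bc} length != {self.barcode_length}")
            if support < 0:
                raise ValueError("read_support must be >= 0")

    def __len__(self) -> int:
        return len(self.entries)

    def variants_of(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for bc, (vid, _) in self.entries.items():
            out.setdefault(vid, []).append(bc)
        return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def extract_window(
    genome_sequence: str,
    tss: int,
    strand: str,
    up: int = DEFAULT_UP,
    down: int = DEFAULT_DOWN,
    gene: str = "",
    promoter_name: str = "",
) -> PromoterWindow:
    """Extract the TSS-anchored window from a genome sequence.

    On the plus strand the window is ``genome[tss-up : tss+down]``; on the
    minus strand the mirrored genomic segment is taken and
    reverse-complemented so that "upstream" is always in transcription
    orientation.  The TSS base sits at array index ``up`` in both cases.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    n = len(genome_sequence)
    if strand == "+":
        start, stop = tss - up, tss + down
    else:
        start, stop = tss - down + 1, tss + up + 1
    if start < 0 or stop > n:
        raise IndexError(
            f"window [{start}, {stop}) out of genome bounds [0, {n}) for tss={tss}"
        )
    segment = genome_sequence[start:stop].upper()
    _check_dna(segment, "genomic segment")
    if strand == "-":
        segment = reverse_complement(segment)
    return PromoterWindow(
        gene=gene,
        promoter_name=promoter_name or (gene + "p" if gene else "promoter"),
        tss_genomic=tss,
        strand=strand,
        sequence=segment,
        up=up,
        down=down,
    )


def mutate_promoter(window: PromoterWindow, cfg: MutagenesisConfig) -> VariantLibrary:
    """Generate the mutant pool: every position mutated independently with
    probability ``cfg.rate``; a mutated base is replaced by one of the three
    alternatives uniformly at random."""
    rng = np.random.default_rng(cfg.seed)
    wt = encode(window.sequence)
    L = len(wt)
    n = cfg.n_variants
    masks = rng.random((n, L)) < cfg.rate
    # offset 1..3 from the wild-type base, mod 4, is uniform over alternatives
    offsets = rng.integers(1, 4, size=(n, L), dtype=np.int8)
    codes = np.where(masks, (wt[None, :] + offsets) % 4, wt[None, :]).astype(np.int8)
    masks = codes != wt[None, :]
    if cfg.include_wildtype:
        codes = np.vstack([wt[None, :], codes])
        masks = np.vstack([np.zeros((1, L), dtype=bool), masks])
    return VariantLibrary(promoter=window, codes=codes, masks=masks, seed=cfg.seed)


def assemble_oligo(
    variant: str,
    variant_id: str = "variant",
    primer_fwd: str = "GCTAGCTCAGTCCTAGGTAC",
    primer_rev: str = "CATGGTACCTGCAGTCGACG",
    site5: str = ENZYME_SITES["SpeI"],
    site3: str = ENZYME_SITES["ApaI"],
    watch_sites: Sequence[str] | None = None,
) -> OligoConstruct:
    """Assemble fwd-primer + 5' site + variant + 3' site + rev-primer.

    Variants containing any watched recognition sequence internally are
    flagged (not rejected): such oligos would be cut during cloning.
    """
    if not primer_fwd or not primer_rev:
        raise ValueError("primers must be non-empty")
    for s in (primer_fwd, primer_rev, site5, site3, variant):
        _check_dna(s)
    if watch_sites is None:
        watch_sites = list(ENZYME_SITES.values())
    flags = [
        f"internal restriction site {site} at {variant.index(site)}"
        for site in watch_sites
        if site in variant
    ]
    full = primer_fwd + site5 + variant + site3 + primer_rev
    return OligoConstruct(variant_id=variant_id, full_sequence=full, flags=flags)


def assign_barcodes(
    library: VariantLibrary,
    barcodes_per_variant: int | tuple[str, float] | Callable[[np.random.Generator, int], np.ndarray] = 3,
    barcode_length: int = DEFAULT_BARCODE_LENGTH,
    seed: int = 0,
    read_support: int = 10,
) -> BarcodeMap:
    """Attach unique random barcodes to every variant.

    ``barcodes_per_variant`` may be a fixed integer, a ``("poisson", mean)``
    spec, or a callable ``f(rng, n) -> counts``.  Duplicate barcodes are
    resampled so the map is collision-free by construction.
    """
    rng = np.random.default_rng(seed)
    n = library.n_variants
    if callable(barcodes_per_variant):
        counts = np.asarray(barcodes_per_variant(rng, n), dtype=np.int64)
    elif isinstance(barcodes_per_variant, tuple):
        kind, mean = barcodes_per_variant
        if kind != "poisson":
            raise ValueError(f"unknown barcode-count distribution {kind!r}")
        counts = rng.poisson(mean, size=n)
    else:
        counts = np.full(n, int(barcodes_per_variant), dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("barcode counts must be non-negative")
    total = int(counts.sum())
    if total > 4 ** barcode_length / 2:
        raise ValueError(
            f"{total} barcodes requested exceeds capacity 4^{barcode_length}/2"
        )
    seen: set[str] = set()
    entries: dict[str, tuple[str, int]] = {}
    ids = library.variant_ids()
    for v, c in enumerate(counts):
        for _ in range(int(c)):
            while True:
                bc = decode(rng.integers(0, 4, size=barcode_length))
                if bc not in seen:
                    break
            seen.add(bc)
            entries[bc] = (ids[v], read_support)
    return BarcodeMap(entries=entries, barcode_length=barcode_length)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_promoter_table(path: str | Path) -> pd.DataFrame:
    """Read promoter metadata TSV (gene, promoter_name, tss, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "promoter_name": str})
    required = {"gene", "promoter_name", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"promoter table missing columns: {sorted(missing)}")
    return df


def write_library_fasta(library: VariantLibrary, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(library.variant(v)), id=vid, description="")
        for v, vid in enumerate(library.variant_ids())
    ]
    SeqIO.write(records, str(path), "fasta")


def write_mask_tsv(library: VariantLibrary, path: str | Path) -> None:
    ids = library.variant_ids()
    with open(path, "w") as fh:
        fh.write("variant_id\tmutated_positions\n")
        for v, vid in enumerate(ids):
            pos = ",".join(str(i) for i in np.flatnonzero(library.masks[v]))
            fh.write(f"{vid}\t{pos}\n")


def write_window_meta(library: VariantLibrary, path: str | Path) -> None:
    w = library.promoter
    pd.DataFrame(
        [
            {
                "gene": w.gene,
                "promoter_name": w.promoter_name,
                "tss": w.tss_genomic,
                "strand": w.strand,
                "up": w.up,
                "down": w.down,
                "sequence": w.sequence,
                "seed": library.seed if library.seed is not None else "",
            }
        ]
    ).to_csv(path, sep="\t", index=False)


def read_library(fasta_path: str | Path, meta_path: str | Path) -> VariantLibrary:
    """Re-read a library written by :func:`write_library_fasta` +
    :func:`write_window_meta`; masks are recomputed from the sequences."""
    meta = pd.read_csv(meta_path, sep="\t").iloc[0]
    window = PromoterWindow(
        gene=str(meta["gene"]),
        promoter_name=str(meta["promoter_name"]),
        tss_genomic=int(meta["tss"]),
        strand=str(meta["strand"]),
        sequence=str(meta["sequence"]),
        up=int(meta["up"]),
        down=int(meta["down"]),
    )
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    codes = np.vstack([encode(str(r.seq)) for r in records])
    wt = encode(window.sequence)
    masks = codes != wt[None, :]
    seed = meta.get("seed", "")
    seed = int(seed) if str(seed) not in ("", "nan") else None
    return VariantLibrary(promoter=window, codes=codes, masks=masks, seed=seed)


def write_barcode_map(bmap: BarcodeMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("barcode\tvariant_id\tread_support\n")
        for bc, (vid, support) in bmap.entries.items():
            fh.write(f"{bc}\t{vid}\t{support}\n")


def read_barcode_map(path: str | Path) -> BarcodeMap:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "variant_id": str})
    entries = {
        row.barcode: (row.variant_id, int(row.read_support)) for row in df.itertuples()
    }
    lengths = {len(bc) for bc in entries}
    if len(lengths) > 1:
        raise ValueError(f"mixed barcode lengths in {path}: {sorted(lengths)}")
    length = lengths.pop() if lengths else DEFAULT_BARCODE_LENGTH
    return BarcodeMap(entries=entries, barcode_length=length)
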