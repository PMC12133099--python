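"""Ground-truth synthetic datasets from thermodynamic promoter models.

Expression of each promoter variant is the equilibrium probability that RNA
polymerase occupies its site, computed from an occupancy model: every site
(RNAP, activators, repressors) carries an additive binding-energy matrix in
k_BT units with wild-type entries zero, a dimensionless Boltzmann weight for
the wild-type sequence, and optional cooperativity with RNAP.  Repressors act
by mutual exclusion of RNAP; activators multiply RNAP-bound states by a
factor omega > 1.  Condition dependence enters through a per-condition active
fraction scaling each transcription factor's weight.

Sequencing is emulated at the variant level: abundances are drawn from a
log-normal spread, DNA counts are multinomial in abundance, RNA counts are
multinomial in abundance x expression rate.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .counts import CountTable
from .library_design import (
    BarcodeMap,
    MutagenesisConfig,
    PromoterWindow,
    VariantLibrary,
    assign_barcodes,
    decode,
    encode,
    mutate_promoter,
)

ROLE_RNAP = "RNAP"
ROLE_ACTIVATOR = "activator"
ROLE_REPRESSOR = "repressor"


@dataclass
class EnergyMatrix:
    """Additive per-position, per-base binding-energy model (k_BT units).

    ``start`` is the promoter-relative label of the first site position;
    ``energies`` has one row per site position and one column per base
    (A, C, G, T), with the wild-type base entry zero at every position.
    """

    start: int
    energies: np.ndarray

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 2 or self.energies.shape[1] != 4:
            raise ValueError("energies must be an (L_site, 4) matrix")
        if (self.energies.min(axis=1) > 0).any():
            raise ValueError("each row must have min energy <= 0 (wild type is 0)")

    def __len__(self) -> int:
        return self.energies.shape[0]

    @property
    def end(self) -> int:
        """Promoter-relative label one past the last site position."""
        return self.start + len(self)

    @classmethod
    def from_window(
        cls,
        window: PromoterWindow,
        start_label: int,
        length: int,
        mismatch_penalty: float = 2.0,
        rng: np.random.Generator | None = None,
        jitter: float = 0.0,
    ) -> "EnergyMatrix":
        """Matrix with zero for the wild-type base and a (possibly jittered)
        penalty for every alternative base."""
        i0 = window.index(start_label)
        if i0 < 0 or i0 + length > len(window):
            raise ValueError("site interval outside the promoter window")
        wt = encode(window.sequence[i0 : i0 + length])
        energies = np.full((length, 4), float(mismatch_penalty))
        if jitter > 0:
            if rng is None:
                rng = np.random.default_rng()
            energies += rng.uniform(-jitter, jitter, size=energies.shape)
        energies[np.arange(length), wt] = 0.0
        return cls(start=start_label, energies=energies)


@dataclass
class SiteSpec:
    """One protein-binding site in an architecture."""

    name: str
    role: str
    matrix: EnergyMatrix
    base_weight: float
    interaction_omega: float = 1.0
    excludes_rnap: bool | None = None

    def __post_init__(self) -> None:
        if self.role not in (ROLE_RNAP, ROLE_ACTIVATOR, ROLE_REPRESSOR):
            raise ValueError(f"unknown site role {self.role!r}")
        if self.base_weight < 0:
            raise ValueError("base_weight must be >= 0")
        if self.interaction_omega <= 0:
            raise ValueError("interaction_omega must be > 0")
        if self.excludes_rnap is None:
            self.excludes_rnap = self.role == ROLE_REPRESSOR

    @property
    def interval(self) -> tuple[int, int]:
        return (self.matrix.start, self.matrix.end)


@dataclass
class ArchitectureSpec:
    """Ground-truth regulatory architecture of one promoter."""

    promoter: PromoterWindow
    sites: list[SiteSpec]
    condition_activity: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rnap = [s for s in self.sites if s.role == ROLE_RNAP]
        if len(rnap) != 1:
            raise ValueError(f"architecture needs exactly one RNAP site, got {len(rnap)}")
        for s in self.sites:
            i0 = self.promoter.index(s.matrix.start)
            if i0 < 0 or i0 + len(s.matrix) > len(self.promoter):
                raise ValueError(f"site {s.name} outside the promoter window")
        for cond, activities in self.condition_activity.items():
            for name, a in activities.items():
                if name not in {s.name for s in self.sites}:
                    raise ValueError(f"activity for unknown site {name!r} in {cond!r}")
                if not 0.0 <= a <= 1.0:
                    raise ValueError("active fractions must be in [0, 1]")
        # overlapping sites are only admissible when mutual exclusion applies
        for a, b in itertools.combinations(self.sites, 2):
            if _overlaps(a.interval, b.interval):
                pair = {a.role, b.role}
                excluded = (
                    ROLE_RNAP in pair
                    and (a.excludes_rnap if b.role == ROLE_RNAP else b.excludes_rnap)
                )
                if not excluded:
                    raise ValueError(
                        f"sites {a.name} and {b.name} overlap without a mutual-exclusion rule"
                    )

    @property
    def rnap(self) -> SiteSpec:
        return next(s for s in self.sites if s.role == ROLE_RNAP)

    def activity(self, condition: str, site: SiteSpec) -> float:
        if site.role == ROLE_RNAP:
            return 1.0
        return self.condition_activity.get(condition, {}).get(site.name, 1.0)

    def ground_truth_sites(self) -> list[dict]:
        return [
            {
                "name": s.name,
                "role": s.role,
                "start": s.matrix.start,
                "end": s.matrix.end,
            }
            for s in self.sites
        ]


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


@dataclass
class SimulationConfig:
    depth_dna: int = 1_000_000
    depth_rna: int = 1_000_000
    abundance_dispersion: float = 0.5
    n_replicates: int = 2
    barcodes_per_variant: int = 0  # 0 = simulate at variant level only

    def __post_init__(self) -> None:
        if self.depth_dna <= 0 or self.depth_rna <= 0:
            raise ValueError("sequencing depths must be > 0")
        if self.abundance_dispersion < 0:
            raise ValueError("abundance_dispersion must be >= 0")


@dataclass
class SyntheticDataset:
    libraries: dict[str, VariantLibrary]
    barcode_maps: dict[str, BarcodeMap]
    count_tables: dict[tuple[str, str, int], CountTable]  # (promoter, condition, rep)
    ground_truth: dict
    seed: int

    def table(self, promoter: str, condition: str, replicate: int) -> CountTable:
        return self.count_tables[(promoter, condition, replicate)]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def site_energy(matrix: EnergyMatrix, subsequence: str | np.ndarray) -> float:
    """Additive binding energy of a site-length subsequence, in k_BT."""
    codes = encode(subsequence) if isinstance(subsequence, str) else np.asarray(subsequence)
    if codes.size != len(matrix):
        raise ValueError(
            f"subsequence length {codes.size} != matrix length {len(matrix)}"
        )
    return float(matrix.energies[np.arange(len(matrix)), codes].sum())


def _site_weights(
    arch: ArchitectureSpec, codes: np.ndarray, condition: str
) -> list[np.ndarray]:
    """Per-site Boltzmann weight for each variant row in ``codes``."""
    weights = []
    for s in arch.sites:
        i0 = arch.promoter.index(s.matrix.start)
        sub = codes[:, i0 : i0 + len(s.matrix)]
        energy = s.matrix.energies[np.arange(len(s.matrix))[None, :], sub].sum(axis=1)
        w = s.base_weight * arch.activity(condition, s) * np.exp(-energy)
        weights.append(w)
    return weights


def expression_rates(
    arch: ArchitectureSpec, codes: np.ndarray, condition: str
) -> np.ndarray:
    """Vectorized occupancy-model expression rate for encoded variants.

    Enumerates all admissible joint occupancy states of the sites: states in
    which RNAP and an excluding site are co-bound are dropped; activator
    states co-bound with RNAP gain a factor omega.  The rate is the summed
    weight of RNAP-bound states over the partition sum.
    """
    codes = np.atleast_2d(np.asarray(codes, dtype=np.int8))
    weights = _site_weights(arch, codes, condition)
    rnap_idx = next(i for i, s in enumerate(arch.sites) if s.role == ROLE_RNAP)
    n_sites = len(arch.sites)
    z_total = np.zeros(codes.shape[0])
    z_bound = np.zeros(codes.shape[0])
    for occupancy in itertools.product((0, 1), repeat=n_sites):
        rnap_on = occupancy[rnap_idx] == 1
        state = np.ones(codes.shape[0])
        admissible = True
        for i, (s, on) in enumerate(zip(arch.sites, occupancy)):
            if not on:
                continue
            if i != rnap_idx and rnap_on and s.excludes_rnap:
                admissible = False
                break
            state = state * weights[i]
            if i != rnap_idx and rnap_on and s.role == ROLE_ACTIVATOR:
                state = state * s.interaction_omega
        if not admissible:
            continue
        z_total += state
        if rnap_on:
            z_bound += state
    return z_bound / z_total


def expression_rate(arch: ArchitectureSpec, variant: str, condition: str) -> float:
    """Occupancy-model expression rate of one variant sequence, in [0, 1]."""
    if len(variant) != len(arch.promoter):
        raise ValueError("variant length differs from promoter window length")
    return float(expression_rates(arch, encode(variant)[None, :], condition)[0])


def simulate_counts(
    library: VariantLibrary,
    rates: np.ndarray,
    cfg: SimulationConfig,
    seed: int,
    condition: str = "sim",
    replicate: int = 0,
) -> CountTable:
    """Draw one replicate of DNA and RNA counts for a library.

    Variant abundances are drawn once per replicate from a log-normal
    distribution; DNA counts are multinomial with probabilities proportional
    to abundance, RNA counts with probabilities proportional to
    abundance x expression rate.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size != library.n_variants:
        raise ValueError("one rate per variant required")
    if (rates < 0).any() or (rates > 1).any():
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    abundance = rng.lognormal(mean=0.0, sigma=cfg.abundance_dispersion, size=rates.size)
    p_dna = abundance / abundance.sum()
    rna_mass = abundance * rates
    total_mass = rna_mass.sum()
    if total_mass == 0:
        raise ValueError("all expression rates are zero; cannot draw RNA counts")
    p_rna = rna_mass / total_mass
    dna = rng.multinomial(cfg.depth_dna, p_dna)
    rna = rng.multinomial(cfg.depth_rna, p_rna)
    return CountTable(
        condition=condition,
        replicate=replicate,
        variant_ids=library.variant_ids(),
        dna=dna,
        rna=rna,
        meta={"seed": seed},
    )


def split_counts_to_barcodes(
    table: CountTable, bmap: BarcodeMap, seed: int
) -> tuple[dict[str, int], dict[str, int]]:
    """Split variant-level counts across each variant's barcodes multinomially."""
    rng = np.random.default_rng(seed)
    by_variant = bmap.variants_of()
    dna_out: dict[str, int] = {}
    rna_out: dict[str, int] = {}
    for vid, dna_c, rna_c in zip(table.variant_ids, table.dna, table.rna):
        bcs = by_variant.get(vid, [])
        if not bcs:
            continue
        p = np.full(len(bcs), 1.0 / len(bcs))
        for out, c in ((dna_out, dna_c), (rna_out, rna_c)):
            parts = rng.multinomial(int(c), p)
            for bc, k in zip(bcs, parts):
                if k:
                    out[bc] = out.get(bc, 0) + int(k)
    return dna_out, rna_out


def generate_dataset(
    archs: Sequence[ArchitectureSpec],
    conditions: Sequence[str],
    cfg: SimulationConfig,
    seed: int = 0,
    mutagenesis: MutagenesisConfig | None = None,
) -> SyntheticDataset:
    """Full synthetic experiment: library design, rates, counts, ground truth."""
    root = np.random.default_rng(seed)
    libraries: dict[str, VariantLibrary] = {}
    barcode_maps: dict[str, BarcodeMap] = {}
    tables: dict[tuple[str, str, int], CountTable] = {}
    truth: dict = {"promoters": {}, "seed": seed}
    for arch in archs:
        name = arch.promoter.promoter_name
        base = mutagenesis or MutagenesisConfig()
        mcfg = MutagenesisConfig(
            rate=base.rate,
            n_variants=base.n_variants,
            include_wildtype=base.include_wildtype,
            seed=int(root.integers(2**31)),
        )
        library = mutate_promoter(arch.promoter, mcfg)
        libraries[name] = library
        if cfg.barcodes_per_variant > 0:
            barcode_maps[name] = assign_barcodes(
                library,
                barcodes_per_variant=cfg.barcodes_per_variant,
                seed=int(root.integers(2**31)),
            )
        truth["promoters"][name] = {
            "sites": arch.ground_truth_sites(),
            "condition_activity": arch.condition_activity,
            "library_seed": mcfg.seed,
        }
        for condition in conditions:
            rates = expression_rates(arch, library.codes, condition)
            for rep in range(cfg.n_replicates):
                tables[(name, condition, rep)] = simulate_counts(
                    library,
                    rates,
                    cfg,
                    seed=int(root.integers(2**31)),
                    condition=condition,
                    replicate=rep,
                )
    return SyntheticDataset(
        libraries=libraries,
        barcode_maps=barcode_maps,
        count_tables=tables,
        ground_truth=truth,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write count tables (TSV), ground-truth sites (BED) and a manifest."""
    from .library_design import write_barcode_map, write_library_fasta, write_window_meta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": dataset.seed, "tables": []}
    for name, library in dataset.libraries.items():
        write_library_fasta(library, outdir / f"{name}.library.fa")
        write_window_meta(library, outdir / f"{name}.window.tsv")
        if name in dataset.barcode_maps:
            write_barcode_map(dataset.barcode_maps[name], outdir / f"{name}.barcodes.tsv")
    with open(outdir / "ground_truth.bed", "w") as fh:
        for name, info in dataset.ground_truth["promoters"].items():
            for site in info["sites"]:
                fh.write(
                    f"{name}\t{site['start']}\t{site['end']}\t"
                    f"{site['name']}|{site['role']}\t0\t+\n"
                )
    for (name, condition, rep), table in dataset.count_tables.items():
        fname = f"{name}.{condition}.rep{rep}.counts.tsv"
        table.to_tsv(outdir / fname)
        manifest["tables"].append(
            {
                "promoter": name,
                "condition": condition,
                "replicate": rep,
                "file": fname,
                "seed": table.meta.get("seed"),
            }
        )
    manifest["ground_truth"] = dataset.ground_truth
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Architecture config parsing (YAML/JSON)
# ---------------------------------------------------------------------------

def arch_from_config(doc: Mapping) -> ArchitectureSpec:
    """Build an ArchitectureSpec from a parsed YAML/JSON mapping.

    Schema::

        promoter:
          gene: xylA            # optional
          promoter_name: xylAp
          sequence: ACGT...     # length up+down; or 'random' with a seed
          up: 115
          down: 45
        sites:
          - {name: rnap, role: RNAP, start: -35, length: 30,
             base_weight: 0.05, mismatch_penalty: 1.5}
          - {name: rep1, role: repressor, start: -75, length: 15,
             base_weight: 50.0}
        condition_activity:
          condA: {rep1: 1.0}
          condB: {rep1: 0.0}
    """
    p = doc["promoter"]
    up = int(p.get("up", 115))
    down = int(p.get("down", 45))
    sequence = p.get("sequence", "random")
    if sequence == "random":
        rng = np.random.default_rng(int(p.get("seed", 0)))
        sequence = decode(rng.integers(0, 4, size=up + down))
    window = PromoterWindow(
        gene=str(p.get("gene", "")),
        promoter_name=str(p.get("promoter_name", "promoter")),
        tss_genomic=int(p.get("tss", up)),
        strand=str(p.get("strand", "+")),
        sequence=sequence,
        up=up,
        down=down,
    )
    sites = []
    for s in doc["sites"]:
        matrix = EnergyMatrix.from_window(
            window,
            start_label=int(s["start"]),
            length=int(s["length"]),
            mismatch_penalty=float(s.get("mismatch_penalty", 2.0)),
        )
        sites.append(
            SiteSpec(
                name=str(s["name"]),
                role=str(s["role"]),
                matrix=matrix,
                base_weight=float(s["base_weight"]),
                interaction_omega=float(s.get("omega", 1.0)),
                excludes_rnap=s.get("excludes_rnap"),
            )
        )
    activity = {
        str(c): {str(k): float(v) for k, v in acts.items()}
        for c, acts in doc.get("condition_activity", {}).items()
    }
    return ArchitectureSpec(promoter=window, sites=sites, condition_activity=activity)
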