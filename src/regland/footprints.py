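"""Per-position information footprints and expression-shift matrices.

The information footprint is, at each promoter position, the mutual
information (in bits) between a base's mutation status (wild-type vs
mutated) and the sequencing read source (DNA vs RNA), computed from
per-variant count tables.  The expression-shift matrix records, per position
and substitute base, the fractional change in mean normalized expression of
variants carrying that base relative to variants carrying the wild-type
base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CountTable
from .library_design import VariantLibrary, encode

DEFAULT_ALPHA = 1.0
DEFAULT_SIGMA = 3.0
KERNEL_TRUNCATE = 4.0


@dataclass
class Footprint:
    promoter: str
    condition: str
    replicate: int
    labels: np.ndarray          # promoter-relative position labels
    mi: np.ndarray              # bits
    mi_smoothed: np.ndarray | None = None
    shift: np.ndarray | None = None  # (L, 4), wild-type entries 0, missing NaN
    alpha: float = DEFAULT_ALPHA
    sigma: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.mi = np.asarray(self.mi, dtype=float)
        if self.labels.shape != self.mi.shape:
            raise ValueError("labels and mi must have equal length")

    def __len__(self) -> int:
        return self.mi.size

    def smoothed(self, sigma: float = DEFAULT_SIGMA) -> "Footprint":
        self.mi_smoothed = smooth_footprint(self.mi, sigma)
        self.sigma = sigma
        return self

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"position": self.labels, "mi": self.mi})
        if self.mi_smoothed is not None:
            df["mi_smoothed"] = self.mi_smoothed
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, promoter: str = "", condition: str = "", replicate: int = 0
    ) -> "Footprint":
        df = pd.read_csv(path, sep="\t")
        fp = cls(
            promoter=promoter,
            condition=condition,
            replicate=replicate,
            labels=df["position"].to_numpy(),
            mi=df["mi"].to_numpy(),
        )
        if "mi_smoothed" in df.columns:
            fp.mi_smoothed = df["mi_smoothed"].to_numpy()
        return fp

    def shift_to_tsv(self, path: str | Path) -> None:
        if self.shift is None:
            raise ValueError("no shift matrix computed")
        pd.DataFrame(
            self.shift, columns=["A", "C", "G", "T"]
        ).assign(position=self.labels)[["position", "A", "C", "G", "T"]].to_csv(
            path, sep="\t", index=False
        )


def mutation_indicators(library: VariantLibrary) -> np.ndarray:
    """(L, V) boolean table: entry [i, v] is True iff variant v is mutated
    at position i."""
    return library.masks.T.copy()


def _entropy2(p: np.ndarray, axis=None) -> np.ndarray:
    """Shannon entropy in bits with the 0 log 0 = 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=axis)


def information_footprint(
    counts: CountTable,
    indicators: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Mutual information (bits) per position between mutation status and
    read source, from the 2x2 joint counts

        n(m, s) = sum over variants with status m of count_s(v) + alpha

    with m in {wt, mut} and s in {DNA, RNA}.
    """
    indicators = np.asarray(indicators, dtype=bool)
    L, V = indicators.shape
    if counts.n_variants != V:
        raise ValueError(
            f"count table covers {counts.n_variants} variants, indicators {V}"
        )
    dna = counts.dna.astype(float)
    rna = counts.rna.astype(float)
    ind = indicators.astype(float)
    n = np.empty((L, 2, 2))
    n[:, 1, 0] = ind @ dna            # mutated, DNA
    n[:, 1, 1] = ind @ rna            # mutated, RNA
    n[:, 0, 0] = dna.sum() - n[:, 1, 0]
    n[:, 0, 1] = rna.sum() - n[:, 1, 1]
    n += alpha
    totals = n.sum(axis=(1, 2))
    mi = np.zeros(L)
    ok = totals > 0
    if not ok.all():
        warnings.warn("positions with zero total counts; their MI is set to 0")
    p = n[ok] / totals[ok, None, None]
    pm = p.sum(axis=2)  # marginal over source
    ps = p.sum(axis=1)  # marginal over mutation status
    mi[ok] = _entropy2(pm, axis=1) + _entropy2(ps, axis=1) - _entropy2(p, axis=(1, 2))
    # clip negatives from floating-point cancellation
    return np.maximum(mi, 0.0)


def variant_expression(counts: CountTable, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Pseudocounted normalized expression per variant:
    ((rna+a)/(R+aV)) / ((dna+a)/(D+aV))."""
    V = counts.n_variants
    R = counts.total_rna + alpha * V
    D = counts.total_dna + alpha * V
    return ((counts.rna + alpha) / R) / ((counts.dna + alpha) / D)


def expression_shift_matrix(
    counts: CountTable,
    library: VariantLibrary,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """(L, 4) matrix of fractional expression change per substitute base.

    shift[i, b] = (mean expression of variants with base b at i minus mean
    over variants with the wild-type base) / wild-type-base mean.  Wild-type
    entries are 0; base/position combinations with no representatives are
    NaN (missing).
    """
    if counts.n_variants != library.n_variants:
        raise ValueError("count table and library sizes differ")
    e = variant_expression(counts, alpha)
    codes = library.codes  # (V, L)
    wt = encode(library.promoter.sequence)
    L = library.length
    shift = np.full((L, 4), np.nan)
    for i in range(L):
        col = codes[:, i]
        wt_sel = col == wt[i]
        if not wt_sel.any():
            warnings.warn(f"position {i}: no variants carry the wild-type base")
            continue
        wt_mean = e[wt_sel].mean()
        if wt_mean == 0:
            warnings.warn(f"position {i}: zero wild-type-base mean expression")
            continue
        for b in range(4):
            if b == wt[i]:
                shift[i, b] = 0.0
                continue
            sel = col == b
            if sel.any():
                shift[i, b] = (e[sel].mean() - wt_mean) / wt_mean
    return shift


def gaussian_kernel(sigma: float, truncate: float = KERNEL_TRUNCATE) -> np.ndarray:
    """Normalized discrete Gaussian kernel truncated at ``truncate * sigma``."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    radius = int(np.ceil(truncate * sigma))
    x = np.arange(-radius, radius + 1)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def smooth_footprint(
    mi: np.ndarray, sigma: float = DEFAULT_SIGMA, truncate: float = KERNEL_TRUNCATE
) -> np.ndarray:
    """Gaussian smoothing with edge renormalization: near the boundaries the
    kernel weights are re-divided by their in-window sum, so a constant
    input maps to itself exactly."""
    mi = np.asarray(mi, dtype=float)
    kernel = gaussian_kernel(sigma, truncate)
    radius = kernel.size // 2
    # direct windowed sums handle both short inputs and edge renormalization
    out = np.empty_like(mi)
    L = mi.size
    for i in range(L):
        lo = max(0, i - radius)
        hi = min(L, i + radius + 1)
        w = kernel[(lo - i + radius):(hi - i + radius)]
        out[i] = (mi[lo:hi] * w).sum() / w.sum()
    return out


def footprint_correlation(fp_a: Footprint | np.ndarray, fp_b: Footprint | np.ndarray) -> float:
    """Pearson correlation between two footprints' mi vectors."""
    a = fp_a.mi if isinstance(fp_a, Footprint) else np.asarray(fp_a, dtype=float)
    b = fp_b.mi if isinstance(fp_b, Footprint) else np.asarray(fp_b, dtype=float)
    if a.size != b.size:
        raise ValueError("footprints have different lengths")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance footprint; correlation undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def compute_footprint(
    counts: CountTable,
    library: VariantLibrary,
    alpha: float = DEFAULT_ALPHA,
    sigma: float = DEFAULT_SIGMA,
    with_shift: bool = True,
) -> Footprint:
    """Convenience wrapper: MI footprint + smoothing + shift matrix."""
    aligned = counts.aligned_to(library.variant_ids())
    mi = information_footprint(aligned, mutation_indicators(library), alpha)
    fp = Footprint(
        promoter=library.promoter.promoter_name,
        condition=counts.condition,
        replicate=counts.replicate,
        labels=library.promoter.labels(),
        mi=mi,
        alpha=alpha,
    )
    fp.smoothed(sigma)
    if with_shift:
        fp.shift = expression_shift_matrix(aligned, library, alpha)
    return fp
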