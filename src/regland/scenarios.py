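"""Canonical ground-truth scenarios for testing and benchmarking.

Small factory functions building thermodynamic promoter architectures of the
three footprint classes (extended binding sites, single-position spikes from
emergent -10 elements, and inactive promoters), plus condition-switching
setups for clustering benchmarks.  Tests and the acceptance report both run
the pipeline against these.
"""

from __future__ import annotations

import numpy as np

from .library_design import BASE_INDEX, PromoterWindow, decode, encode
from .synthetic_data import ArchitectureSpec, EnergyMatrix, SiteSpec
from .tss_scan import MINUS10_CONSENSUS

DEFAULT_RNAP_START = -35
DEFAULT_RNAP_LEN = 30
DEFAULT_SITE_START = -75
DEFAULT_SITE_LEN = 15


def random_window(
    seed: int, up: int = 115, down: int = 45, name: str = "synthp", gene: str = "syn"
) -> PromoterWindow:
    rng = np.random.default_rng(seed)
    return PromoterWindow(
        gene=gene,
        promoter_name=name,
        tss_genomic=up,
        strand="+",
        sequence=decode(rng.integers(0, 4, size=up + down)),
        up=up,
        down=down,
    )


def repressor_architecture(
    window: PromoterWindow,
    site_start: int = DEFAULT_SITE_START,
    site_len: int = DEFAULT_SITE_LEN,
    rnap_start: int = DEFAULT_RNAP_START,
    rnap_len: int = DEFAULT_RNAP_LEN,
    rnap_weight: float = 0.05,
    repressor_weight: float = 150.0,
    rnap_penalty: float = 1.5,
    repressor_penalty: float = 1.5,
    active_condition: str = "active",
    inactive_condition: str = "inactive",
) -> ArchitectureSpec:
    """RNAP plus one mutually exclusive repressor, active in one condition."""
    rnap = SiteSpec(
        name="rnap",
        role="RNAP",
        matrix=EnergyMatrix.from_window(window, rnap_start, rnap_len, rnap_penalty),
        base_weight=rnap_weight,
    )
    rep = SiteSpec(
        name="rep1",
        role="repressor",
        matrix=EnergyMatrix.from_window(window, site_start, site_len, repressor_penalty),
        base_weight=repressor_weight,
    )
    return ArchitectureSpec(
        promoter=window,
        sites=[rnap, rep],
        condition_activity={
            active_condition: {"rep1": 1.0},
            inactive_condition: {"rep1": 0.0},
        },
    )


def activator_architecture(
    window: PromoterWindow,
    site_start: int = DEFAULT_SITE_START,
    site_len: int = DEFAULT_SITE_LEN,
    rnap_start: int = DEFAULT_RNAP_START,
    rnap_len: int = DEFAULT_RNAP_LEN,
    rnap_weight: float = 0.02,
    activator_weight: float = 5.0,
    omega: float = 50.0,
    active_condition: str = "active",
    inactive_condition: str = "inactive",
) -> ArchitectureSpec:
    """RNAP plus a cooperative activator (omega > 1)."""
    rnap = SiteSpec(
        name="rnap",
        role="RNAP",
        matrix=EnergyMatrix.from_window(window, rnap_start, rnap_len, 1.5),
        base_weight=rnap_weight,
    )
    act = SiteSpec(
        name="act1",
        role="activator",
        matrix=EnergyMatrix.from_window(window, site_start, site_len, 3.0),
        base_weight=activator_weight,
        interaction_omega=omega,
    )
    return ArchitectureSpec(
        promoter=window,
        sites=[rnap, act],
        condition_activity={
            active_condition: {"act1": 1.0},
            inactive_condition: {"act1": 0.0},
        },
    )


def inactive_architecture(window: PromoterWindow, basal_weight: float = 1e-3) -> ArchitectureSpec:
    """No sequence-dependent site: flat basal expression, pure noise footprint."""
    matrix = EnergyMatrix(start=DEFAULT_RNAP_START, energies=np.zeros((DEFAULT_RNAP_LEN, 4)))
    rnap = SiteSpec(name="rnap", role="RNAP", matrix=matrix, base_weight=basal_weight)
    return ArchitectureSpec(promoter=window, sites=[rnap], condition_activity={})


def spike_architecture(
    window: PromoterWindow,
    spike_label: int = -68,
    reward: float = 8.0,
    basal_weight: float = 1e-4,
) -> ArchitectureSpec:
    """Single-position signal: one specific substitution strongly boosts RNAP.

    The RNAP matrix is flat except at ``spike_label`` where one alternative
    base carries a large negative (favorable) energy, so only variants with
    that mutation express: the hallmark of an emergent TSS footprint.
    """
    start = spike_label - 3
    length = 10
    i_site = window.index(spike_label) - window.index(start)
    wt = encode(window.sequence[window.index(start) : window.index(start) + length])
    energies = np.zeros((length, 4))
    alt = (wt[i_site] + 1) % 4
    energies[i_site, alt] = -reward
    matrix = EnergyMatrix(start=start, energies=energies)
    rnap = SiteSpec(name="rnap", role="RNAP", matrix=matrix, base_weight=basal_weight)
    return ArchitectureSpec(promoter=window, sites=[rnap], condition_activity={})


def emergent_tss_window(
    seed: int,
    hexamer_label_start: int = -70,
    up: int = 115,
    down: int = 45,
    name: str = "emergentp",
) -> tuple[PromoterWindow, int, str, str]:
    """Random window carrying a TATAAA hexamer one key mutation from consensus.

    Returns (window, mutation label, from base, to base): mutating the final
    A to T completes the TATAAT key positions.  Any accidental hexamer
    already matching all key positions elsewhere is left untouched; callers
    that need uniqueness should filter candidates by position.
    """
    rng = np.random.default_rng(seed)
    seq = list(decode(rng.integers(0, 4, size=up + down)))
    near = MINUS10_CONSENSUS[:-1] + "A"  # TATAAA: keys 1,2 match, key 6 fails
    i0 = hexamer_label_start + up
    seq[i0 : i0 + 6] = near
    window = PromoterWindow(
        gene="emergent",
        promoter_name=name,
        tss_genomic=up,
        strand="+",
        sequence="".join(seq),
        up=up,
        down=down,
    )
    return window, hexamer_label_start + 5, "A", "T"


def emergent_tss_architecture(
    window: PromoterWindow,
    mutation_label: int,
    to_base: str,
    reward: float = 8.0,
    basal_weight: float = 1e-4,
) -> ArchitectureSpec:
    """Thermodynamic model rewarding the -10-completing base."""
    start = mutation_label - 5
    length = 8
    i0 = window.index(start)
    i_site = window.index(mutation_label) - i0
    energies = np.zeros((length, 4))
    energies[i_site, BASE_INDEX[to_base]] = -reward
    matrix = EnergyMatrix(start=start, energies=energies)
    rnap = SiteSpec(name="rnap", role="RNAP", matrix=matrix, base_weight=basal_weight)
    return ArchitectureSpec(promoter=window, sites=[rnap], condition_activity={})


def switching_architecture(
    window: PromoterWindow,
    normal_conditions: list[str],
    switch_condition: str,
    site_a_start: int = DEFAULT_SITE_START,
    site_b_start: int = 5,
    site_len: int = DEFAULT_SITE_LEN,
) -> ArchitectureSpec:
    """Two repressors at different locations, swapped between condition groups.

    In the normal conditions only repressor A is active; in the switch
    condition (a stationary-phase-like state) only repressor B is.  The
    footprint peak therefore relocates, making the switch condition separate
    out in clustering.
    """
    rnap = SiteSpec(
        name="rnap",
        role="RNAP",
        matrix=EnergyMatrix.from_window(window, DEFAULT_RNAP_START, DEFAULT_RNAP_LEN, 1.5),
        base_weight=0.05,
    )
    rep_a = SiteSpec(
        name="repA",
        role="repressor",
        matrix=EnergyMatrix.from_window(window, site_a_start, site_len, 3.0),
        base_weight=20.0,
    )
    rep_b = SiteSpec(
        name="repB",
        role="repressor",
        matrix=EnergyMatrix.from_window(window, site_b_start, site_len, 3.0),
        base_weight=20.0,
    )
    activity = {c: {"repA": 1.0, "repB": 0.0} for c in normal_conditions}
    activity[switch_condition] = {"repA": 0.0, "repB": 1.0}
    return ArchitectureSpec(
        promoter=window, sites=[rnap, rep_a, rep_b], condition_activity=activity
    )
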