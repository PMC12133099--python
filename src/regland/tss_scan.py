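"""Detection of emergent transcription start sites created by one mutation.

The sigma-70 -10 element has the consensus hexamer TATAAT, of which the
first two bases and the last base dominate binding.  A single substitution
creates a new transcription start site when, afterwards, all three of those
key positions match the consensus while at least one failed beforehand.
This module scans a promoter window for every such mutation and optionally
corroborates candidates against an expression-shift matrix from a condition
in which the native promoter is inactive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .library_design import BASE_INDEX, DNA_ALPHABET, PromoterWindow

MINUS10_CONSENSUS = "TATAAT"

#: 1-based hexamer positions whose consensus match is required (first two
#: bases and the last base of TATAAT).
KEY_POSITIONS = (1, 2, 6)

#: Predicted TSS sits this many bases downstream of the hexamer's last base
#: (canonical sigma-70 spacing; a convention, not a fitted value).
TSS_OFFSET = 7

DEFAULT_SPIKE_THRESHOLD = 5.0


@dataclass
class Minus10Match:
    hexamer_start: int                    # promoter array index
    key_matches: frozenset[int]           # subset of KEY_POSITIONS matching
    full_matches: int                     # count of all 6 positions matching

    @property
    def all_keys(self) -> bool:
        return self.key_matches == frozenset(KEY_POSITIONS)


@dataclass
class TssCandidate:
    position_label: int
    from_base: str
    to_base: str
    hexamer_label_start: int              # promoter-relative labels, half-open
    hexamer_label_end: int
    predicted_tss_label: int
    shift_support: float | None = None
    supported: bool | None = None


def score_minus10(
    hexamer: str, key_positions: tuple[int, ...] = KEY_POSITIONS
) -> Minus10Match:
    """Compare a hexamer against the TATAAT consensus."""
    if len(hexamer) != 6:
        raise ValueError(f"hexamer must have length 6, got {len(hexamer)}")
    matches = [i + 1 for i in range(6) if hexamer[i] == MINUS10_CONSENSUS[i]]
    return Minus10Match(
        hexamer_start=0,
        key_matches=frozenset(m for m in matches if m in key_positions),
        full_matches=len(matches),
    )


def scan_emergent_tss(
    window: PromoterWindow,
    key_positions: tuple[int, ...] = KEY_POSITIONS,
) -> list[TssCandidate]:
    """All single substitutions that complete the -10 key positions.

    For every position, alternative base, and overlapping hexamer, a
    candidate is reported iff the wild-type hexamer fails at least one key
    position and the mutated hexamer matches all of them.  Identical
    (mutation, hexamer) pairs are deduplicated.
    """
    seq = window.sequence
    L = len(seq)
    required = frozenset(key_positions)
    candidates: list[TssCandidate] = []
    seen: set[tuple[int, str, int]] = set()
    for h in range(L - 5):
        wt_hex = seq[h : h + 6]
        wt_keys = score_minus10(wt_hex, key_positions).key_matches
        if wt_keys == required:
            continue  # already complete: no key position left to create
        for offset in range(6):
            i = h + offset
            wt_base = seq[i]
            for alt in DNA_ALPHABET:
                if alt == wt_base:
                    continue
                mut_hex = wt_hex[:offset] + alt + wt_hex[offset + 1 :]
                if score_minus10(mut_hex, key_positions).key_matches != required:
                    continue
                key = (i, alt, h)
                if key in seen:
                    continue
                seen.add(key)
                candidates.append(
                    TssCandidate(
                        position_label=window.label(i),
                        from_base=wt_base,
                        to_base=alt,
                        hexamer_label_start=window.label(h),
                        hexamer_label_end=window.label(h + 5) + 1,
                        predicted_tss_label=window.label(h + 5) + TSS_OFFSET,
                    )
                )
    return candidates


def corroborate_with_shift(
    candidates: list[TssCandidate],
    shift: np.ndarray,
    window: PromoterWindow,
    spike_threshold: float = DEFAULT_SPIKE_THRESHOLD,
) -> list[TssCandidate]:
    """Annotate candidates with the expression shift of their mutation.

    A candidate is flagged supported when its shift value is a positive
    outlier, exceeding ``spike_threshold`` times the median absolute shift
    over all non-wild-type, non-missing entries.
    """
    shift = np.asarray(shift, dtype=float)
    nonwt = shift[(shift != 0.0) & np.isfinite(shift)]
    scale = float(np.median(np.abs(nonwt))) if nonwt.size else 0.0
    for cand in candidates:
        i = window.index(cand.position_label)
        value = shift[i, BASE_INDEX[cand.to_base]]
        if np.isnan(value):
            cand.shift_support = None
            cand.supported = None
        else:
            cand.shift_support = float(value)
            cand.supported = bool(value > spike_threshold * scale and value > 0)
    return candidates


def write_candidates_tsv(candidates: list[TssCandidate], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "position": c.position_label,
                "from_base": c.from_base,
                "to_base": c.to_base,
                "hexamer_start": c.hexamer_label_start,
                "hexamer_end": c.hexamer_label_end,
                "predicted_tss": c.predicted_tss_label,
                "shift": c.shift_support if c.shift_support is not None else "",
                "supported": c.supported if c.supported is not None else "",
            }
            for c in candidates
        ]
    ).to_csv(path, sep="\t", index=False)
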