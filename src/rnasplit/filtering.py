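"""Filtering of parsed RNA chains for deep-learning suitability.

Four predicates remove chains: too short, resolution too low, composition
dominated by one nucleotide, or too many unknown residues; NMR structures are
excluded by default because they carry no well-defined resolution.  All
removals use strict inequalities — a chain of exactly 32 residues, exactly
9.0 Å, exactly 80 % single-nucleotide or exactly 30 % unknown is kept.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .mmcif_io import CANONICAL, RnaChain

#: Rejection reason tags, in reporting order.
REASONS = ("length", "resolution", "composition", "unknown", "nmr")


@dataclass(frozen=True)
class FilterConfig:
    min_length: int = 32
    max_resolution: float = 9.0
    max_single_nt_fraction: float = 0.80
    max_unknown_fraction: float = 0.30
    include_nmr: bool = False

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_resolution <= 0:
            raise ValueError("max_resolution must be > 0")
        for frac in (self.max_single_nt_fraction, self.max_unknown_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class FilterReport:
    """Per-chain rejection reasons plus aggregate tallies.

    A chain is kept iff its reason list is empty; one chain may carry several
    reasons, so reason tallies can sum to more than the number of rejected
    chains.
    """

    reasons: dict[str, list[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        tally = Counter()
        for rs in self.reasons.values():
            tally.update(rs)
        return {r: tally.get(r, 0) for r in REASONS}

    @property
    def n_rejected(self) -> int:
        return sum(1 for rs in self.reasons.values() if rs)

    @property
    def n_kept(self) -> int:
        return sum(1 for rs in self.reasons.values() if not rs)

    def to_dict(self) -> dict:
        return {
            "per_chain": self.reasons,
            "counts": self.counts,
            "n_kept": self.n_kept,
            "n_rejected": self.n_rejected,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def chain_reasons(chain: RnaChain, config: FilterConfig) -> list[str]:
    """Rejection reasons for one chain (empty list = kept)."""
    reasons: list[str] = []
    if chain.length < config.min_length:
        reasons.append("length")

    resolution = chain.resolution
    if chain.is_nmr and not config.include_nmr:
        # NMR rejection gets its own tag; the missing resolution is implied
        reasons.append("nmr")
    else:
        if chain.is_nmr and resolution is None:
            resolution = 0.0  # NMR admitted: interpret as 0.0 Å
        if resolution is None or resolution > config.max_resolution:
            reasons.append("resolution")

    if chain.length > 0:
        counts = Counter(chain.sequence)
        top = max((counts.get(nt, 0) for nt in CANONICAL), default=0)
        if top / chain.length > config.max_single_nt_fraction:
            reasons.append("composition")
        if chain.n_unknown / chain.length > config.max_unknown_fraction:
            reasons.append("unknown")
    return reasons


def filter_chains(
    chains: Sequence[RnaChain], config: FilterConfig | None = None
) -> tuple[list[RnaChain], FilterReport]:
    """Split chains into the kept set and a full rejection report."""
    config = config or FilterConfig()
    report = FilterReport()
    kept: list[RnaChain] = []
    for chain in chains:
        rs = chain_reasons(chain, config)
        report.reasons[chain.full_id] = rs
        if not rs:
            kept.append(chain)
    return kept, report
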