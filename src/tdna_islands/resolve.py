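"""Resolution phase: one island per tDNA unless a tandem array is discernible,
plus island naming and summary statistics.

Multiple surviving candidates at one tDNA usually reflect one island whose
fragment matched several places; they are resolved to a single island.  The
exception is a tandem array: islands stacked at one tDNA, recognisable when
each successive inter-fragment segment carries its own integrase gene and ends
at its own displaced fragment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .intervals import Interval, contains, overlaps
from .model import (
    AA_THREE_TO_ONE,
    CandidateIsland,
    IntegraseCall,
    IslandRecord,
    PipelineConfig,
    SummaryStats,
)

log = logging.getLogger(__name__)


@dataclass
class ResolvedIsland:
    """A resolved (possibly tandem-member) island before naming."""

    candidate: CandidateIsland
    interval: Interval
    length: int
    tandem_index: Optional[Tuple[int, int]]
    integrase_count: int


def _count_integrases(iv: Interval, integrases: List[IntegraseCall], L: int) -> int:
    return sum(1 for ig in integrases if overlaps(iv, ig.orf_interval, L))


def resolve_tdna(
    survivors: List[CandidateIsland],
    integrases: List[IntegraseCall],
    replicon_length: int,
) -> List[ResolvedIsland]:
    """Resolve all surviving candidates that share one tDNA.

    Candidates are ordered by fragment distance from the gene (nearest first,
    i.e. increasing candidate length).  If every successive segment between
    fragments holds its own admitted integrase and contains its own fragment,
    the candidates describe a tandem array and each member is returned with its
    (k of n) index.  Otherwise a single winner is chosen: highest fragment
    score, then shortest island, then leftmost start.
    """
    if not survivors:
        return []
    L = replicon_length
    if len(survivors) == 1:
        c = survivors[0]
        return [
            ResolvedIsland(
                candidate=c,
                interval=c.island_interval,
                length=c.length,
                tandem_index=None,
                integrase_count=_count_integrases(c.island_interval, integrases, L),
            )
        ]
    ordered = sorted(survivors, key=lambda c: (c.length, c.island_interval.start))
    members = _try_tandem(ordered, integrases, L)
    if members is not None:
        return members
    winner = max(
        survivors,
        key=lambda c: (c.fragment.score, -c.length, -c.island_interval.start),
    )
    return [
        ResolvedIsland(
            candidate=winner,
            interval=winner.island_interval,
            length=winner.length,
            tandem_index=None,
            integrase_count=_count_integrases(winner.island_interval, integrases, L),
        )
    ]


def _try_tandem(
    ordered: List[CandidateIsland], integrases: List[IntegraseCall], L: int
) -> Optional[List[ResolvedIsland]]:
    """Partition the span into per-member segments, or None if not a tandem."""
    first = ordered[0]
    same_geometry = all(
        c.fragment.side == first.fragment.side
        and c.fragment_downstream == first.fragment_downstream
        and c.fragment.subject_strand == first.fragment.subject_strand
        for c in ordered
    )
    if not same_geometry:
        return None
    n = len(ordered)
    members: List[ResolvedIsland] = []
    # Right-arc islands grow rightward from the tDNA's forward end; left-arc
    # islands grow leftward from its forward start.
    right_arc = (first.tdna.strand == "+") == first.fragment_downstream
    prev: Optional[CandidateIsland] = None
    for k, c in enumerate(ordered, start=1):
        if prev is None:
            seg = c.island_interval
            seg_len = c.length
        else:
            if c.length <= prev.length:
                return None
            seg_len = c.length - prev.length
            if right_arc:
                start = prev.fragment.subject_interval.end % L
                seg = Interval(start, c.island_interval.end)
            else:
                seg = Interval(c.island_interval.start, prev.fragment.subject_interval.start or L)
        if not contains(seg, c.fragment.subject_interval, L):
            return None
        n_int = _count_integrases(seg, integrases, L)
        if n_int == 0:
            return None
        members.append(
            ResolvedIsland(
                candidate=c, interval=seg, length=seg_len,
                tandem_index=(k, n), integrase_count=n_int,
            )
        )
        prev = c
    return members


def site_letter(isotype: str, config: Optional[PipelineConfig] = None) -> str:
    """One-letter integration-site code for an isotype ('Ser' or 'S' -> 'S')."""
    if isotype.lower() == "tmrna":
        return (config or PipelineConfig()).tmrna_site_letter
    if len(isotype) == 1:
        return isotype.upper()
    for three, one in AA_THREE_TO_ONE.items():
        if three.lower() == isotype.lower():
            return one
    raise ValueError(f"unrecognised isotype {isotype!r}")


def kbp_component(length_bp: int) -> int:
    """Island length in kbp, rounded half away from zero (49591 -> 50)."""
    return int(math.floor(length_bp / 1000 + 0.5))


def name_island(
    genus: str,
    species: str,
    serial: int,
    length_bp: int,
    isotype: str,
    config: Optional[PipelineConfig] = None,
) -> str:
    """Build an island name like ``Eco661_50S``.

    Nickname: first letter of the genus (skipping a leading 'Candidatus'
    token) plus the first two letters of the species, then the strain serial;
    suffix: island length in kbp and the one-letter site code of the target.
    """
    tokens = [t for t in genus.split() if t]
    if tokens and tokens[0].lower() == "candidatus":
        tokens = tokens[1:]
    if not tokens:
        raise ValueError("genus is required for naming")
    if not species:
        raise ValueError("species is required for naming")
    nickname = tokens[0][0].upper() + species[:2].lower()
    return f"{nickname}{serial}_{kbp_component(length_bp)}{site_letter(isotype, config)}"


def mean_per_positive(total_islands: int, genomes_with_island: int) -> float:
    """Mean islands per island-bearing genome, to 2 decimals (half away from 0)."""
    if genomes_with_island == 0:
        return 0.0
    x = total_islands / genomes_with_island
    return math.floor(x * 100 + 0.5) / 100


def summarize(islands: List[IslandRecord], genomes_scanned: int) -> SummaryStats:
    """Tabulate the island set the way the database's headline table does."""
    stats = SummaryStats()
    stats.total_islands = len(islands)
    positive = {isl.replicon_id for isl in islands}
    stats.genomes_with_island = len(positive)
    stats.mean_defined = bool(positive)
    stats.mean_islands_per_positive_genome = mean_per_positive(
        stats.total_islands, stats.genomes_with_island
    )
    arrays: Dict[Tuple[str, str], int] = {}
    for isl in islands:
        if isl.damaged:
            stats.islands_damaged += 1
        if isl.fragment_side == "three_prime":
            stats.islands_3prime += 1
        elif isl.fragment_side == "five_prime":
            stats.islands_5prime += 1
        if isl.subsite == "A":
            stats.islands_A += 1
        elif isl.subsite == "J":
            stats.islands_J += 1
        else:
            stats.islands_subsite_na += 1
        if isl.tandem_index is not None:
            arrays[(isl.replicon_id, isl.target_id)] = isl.tandem_index[1]
    stats.tandem_ge2 = sum(1 for n in arrays.values() if n >= 2)
    stats.tandem_ge3 = sum(1 for n in arrays.values() if n >= 3)
    if genomes_scanned < stats.genomes_with_island:
        log.warning("genomes_scanned (%d) below positive-genome count", genomes_scanned)
    return stats
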