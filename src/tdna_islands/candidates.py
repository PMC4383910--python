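"""Candidate-island construction and the filtering phase.

Each (tDNA, displaced-fragment) pair brackets a candidate island.  Candidates
then pass a cascade of seven pure predicates, in order: integrase, CDS, tDNA,
length, internal-fragment, configuration, orientation.  Because every filter
is a pure function of the candidate and its context, the accepted set is
independent of evaluation order; the cascade order only shapes the rejection
counts reported per filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .intervals import Interval, contains, forward_gap, overlaps
from .model import (
    FILTER_ORDER,
    CandidateIsland,
    DomainCall,
    FilterTrace,
    FragmentHit,
    IntegraseCall,
    PipelineConfig,
    Replicon,
    TdnaGene,
)

log = logging.getLogger(__name__)


@dataclass
class CascadeContext:
    """Everything the filter predicates need besides the candidate itself."""

    replicon: Replicon
    tdnas: List[TdnaGene]
    integrases: List[IntegraseCall]  # already admitted
    domains: List[DomainCall]
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @property
    def L(self) -> int:
        return len(self.replicon)


def build_candidate(
    tdna: TdnaGene, hit: FragmentHit, replicon: Replicon
) -> CandidateIsland:
    """Bracket the island between the intact tDNA and its displaced fragment.

    The island excludes the intact gene and includes the whole fragment, so
    excising the interval and re-joining leaves exactly one intact tDNA.  On a
    circular replicon the shorter of the two arcs is taken.
    """
    L = len(replicon)
    circ = replicon.circular
    t_iv, f_iv = tdna.interval, hit.subject_interval
    if overlaps(t_iv, f_iv, L):
        raise ValueError(
            f"fragment {f_iv} overlaps its own tDNA locus {t_iv}; "
            "self-hits must be removed before candidate construction"
        )
    right_len = forward_gap(t_iv.end % L if circ else t_iv.end, f_iv.end, L, circ)
    left_len = forward_gap(f_iv.start, t_iv.start, L, circ)
    # forward_gap of 0 would mean a zero-length island; treat as invalid arc
    right_len = right_len if right_len else None
    left_len = left_len if left_len else None
    if right_len is None and left_len is None:
        raise ValueError("fragment is not clear of the tDNA on either side")
    if left_len is None or (right_len is not None and right_len <= left_len):
        start = t_iv.end % L if circ else t_iv.end
        island = Interval(start, f_iv.end)
        length = right_len
        right_arc = True
    else:
        island = Interval(f_iv.start, t_iv.start if t_iv.start else (L if circ else t_iv.start))
        length = left_len
        right_arc = False
    downstream = right_arc if tdna.strand == "+" else not right_arc
    return CandidateIsland(
        tdna=tdna,
        fragment=hit,
        island_interval=island,
        length=length,
        fragment_downstream=downstream,
    )


# --- the seven filter predicates -------------------------------------------

def filter_integrase(c: CandidateIsland, ctx: CascadeContext) -> bool:
    """Pass iff the island contains or overlaps an admitted integrase ORF."""
    within = [
        ig
        for ig in ctx.integrases
        if overlaps(c.island_interval, ig.orf_interval, ctx.L)
    ]
    c.integrases_within = within
    return bool(within)


def filter_cds(c: CandidateIsland, ctx: CascadeContext) -> bool:
    """Fail when the fragment or the gene overlaps a non-integrase Pfam domain.

    True tDNAs and their island-split fragments should not overlap conserved
    protein-coding regions; integrase domains are exempt because some
    integrases extend across attP.
    """
    for dom in ctx.domains:
        if dom.is_integrase:
            continue
        if overlaps(c.fragment.subject_interval, dom.dna_interval, ctx.L):
            return False
        if overlaps(c.tdna.interval, dom.dna_interval, ctx.L):
            return False
    return True


def filter_tdna(c: CandidateIsland, ctx: CascadeContext) -> bool:
    """Fail when the hit falls within (is contained in) a full-length tDNA."""
    for gene in ctx.tdnas:
        if contains(gene.interval, c.fragment.subject_interval, ctx.L):
            return False
    return True


def filter_length(c: CandidateIsland, ctx: CascadeContext) -> bool:
    return ctx.config.min_len <= c.length <= ctx.config.max_len


def filter_internal(c: CandidateIsland, ctx: CascadeContext) -> bool:
    """Integration splits off tDNA *end* fragments; internal hits are rejected."""
    return c.fragment.side in ("five_prime", "three_prime")


def filter_configuration(c: CandidateIsland, ctx: CascadeContext) -> bool:
    """Integration displaces a 3' fragment downstream, a 5' fragment upstream.

    Internal-sided candidates pass through here; their rejection belongs to
    the internal-fragment filter (keeps each rejection attributable to exactly
    one filter without changing the accepted set).
    """
    if c.fragment.side == "internal":
        return True
    if c.fragment.side == "three_prime":
        return c.fragment_downstream
    return not c.fragment_downstream


def filter_orientation(c: CandidateIsland, ctx: CascadeContext) -> bool:
    return c.fragment.subject_strand == c.tdna.strand


FILTERS = {
    "integrase": filter_integrase,
    "cds": filter_cds,
    "tdna": filter_tdna,
    "length": filter_length,
    "internal": filter_internal,
    "configuration": filter_configuration,
    "orientation": filter_orientation,
}


def classify_subsite(
    c: CandidateIsland, config: PipelineConfig, replicon_length: Optional[int] = None
) -> str:
    """Call the att crossover subsite: anticodon region (A) or T/acceptor (J).

    The crossover is the fragment's proximal query boundary in tDNA-local
    coordinates.  Crossovers in the anticodon-arm window (default fractional
    position [0.30, 0.60) of the gene) are A; at or beyond the window, J
    (T-loop and T/acceptor junction are merged into J).  tmRNA targets and
    internal fragments get NA.
    """
    if c.tdna.kind != "tRNA" or c.fragment.side == "internal":
        c.subsite = "NA"
        if c.tdna.kind != "tRNA":
            log.debug("subsite NA for tmRNA target %s", c.tdna.id)
        return c.subsite
    L = c.tdna.interval.length(replicon_length)
    qs, qe = c.fragment.query_span
    crossover = qs if c.fragment.side == "three_prime" else qe
    frac = crossover / L
    lo, hi = config.subsite_a_window
    if lo <= frac < hi:
        c.subsite = "A"
    else:
        if frac < lo:
            log.warning(
                "tDNA %s: crossover at %.2f of gene length is acceptor-stem-"
                "proximal; calling J", c.tdna.id, frac,
            )
        c.subsite = "J"
    return c.subsite


def run_cascade(
    candidates: List[CandidateIsland],
    ctx: CascadeContext,
    evaluate_all: bool = False,
) -> Tuple[List[CandidateIsland], FilterTrace]:
    """Apply the seven filters in order; return survivors and per-filter counts.

    With ``evaluate_all`` every filter is evaluated for every candidate (full
    audit trace); otherwise filters after the first failure are marked
    not-evaluated.  The survivor set is identical either way.
    """
    trace = FilterTrace()
    alive = list(candidates)
    for name in FILTER_ORDER:
        fn = FILTERS[name]
        trace.entering[name] = len(alive)
        still = []
        rejected = 0
        for c in alive:
            ok = fn(c, ctx)
            c.filter_trace[name] = "pass" if ok else "fail"
            if ok:
                still.append(c)
            else:
                rejected += 1
        trace.rejected[name] = rejected
        alive = still
    for c in candidates:
        for name in FILTER_ORDER:
            if name not in c.filter_trace:
                if evaluate_all:
                    c.filter_trace[name] = "pass" if FILTERS[name](c, ctx) else "fail"
                else:
                    c.filter_trace[name] = "not-evaluated"
    for c in (candidates if evaluate_all else alive):
        classify_subsite(c, ctx.config, ctx.L)
    return alive, trace
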