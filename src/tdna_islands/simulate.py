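"""Seeded generator of replicons with planted, truth-annotated islands.

Each plant reproduces the integration signature the search looks for: an
intact tDNA, an island body carrying an integrase ORF, and the displaced
portion of the tDNA duplicated at the island's distal end.  Decoy plants
perturb exactly one property so that exactly one filter rejects them.

Design notes
------------
* tDNA templates are fixed synthetic 76-nt sequences with pairwise-disjoint
  word vocabularies (7-mers, both strands), so planted genes never cross-hit.
* Background sequence is i.i.d. with configurable GC.  A post-pass mutates any
  background word that collides with a planted gene's 7-mer vocabulary, so
  every seed in the finished replicon points at a planted fragment and truth
  tables stay exact.
* Each planted fragment is flanked by a short run of N.  N matches nothing
  under the search scoring, so no alignment can creep past a designed
  fragment boundary and no seed word can straddle one; planted hits are
  recovered at exactly their designed coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from numba import njit

from .intervals import Interval, shift
from .model import (
    DomainCall,
    IntegraseCall,
    Organism,
    PipelineConfig,
    Replicon,
    TdnaGene,
)
from .search import encode, find_fragment_hits, kmer_codes, revcomp

log = logging.getLogger(__name__)

# Fixed synthetic tDNA templates (76 nt).  Any two templates, and each
# template and its own reverse complement, share no 7-mer.
TEMPLATES = (
    "CCTGATATGTAGCTTAAAGCTCACCCTGAGCTGAACTCTGCCTTTATTGCGGTGGTCGCTACCAACCCGTACACGA",
    "CGCACAAATTAACAACTGGTCTTTAACGATCGGAACTCGATGATGGAGCATAGTTTACCAAGACCCGACCAGCGCG",
    "CAGGTCAAGATAAGATGTACCGGCCCACGGCGATCCGTTTCCCCAGCATGATGCGCTTGGAAACTAGATGGCGGCC",
    "TATGTGCCAGAAAGGTACACAGAGCATTGCCATTTCGACGGAGTCGTCGCGTGAGTGGAGACATCGTCTGCCAGCT",
    "AGGGGCGTAATCATAATGCAACGCGCGATCTTCTGTGATTTATTATGCGGTCTACTCTCCTGGTCACTAATACTAC",
    "AAAAGCCCGCTCAGTGTCTGGGACTGGCTGCCGGCTGGACCTTCTCTAGATTGTTCGGTCACAAAGTATTGCAGCC",
    "TCAATGAGGGCCCGCACATTAAGGCTTCCTATTGGAGTCACTCTTTGACAACAATATATCTTTTAGAGGTTATCGA",
    "CAACTGTTTGGCTTCACGTAATTATTCGCCTCCTTCAGACAATGTTGGTCCCCGGGAGGTCTCTCCGGCATGAAGT",
    "ATGAACATTTGTACATGATACCAGAAGCGTATTTATGAATTGGTATTCCTTGACACGGGCGTGGAACGTAGTACGG",
    "CTGTGTTGCTCGATAGCACTGGCGGTCGCGCCCGAATTAGACGTAAGTTTAAATCGATCTCTCTATGCCACAAGAG",
    "TTAGCGTTGTCCACTTAGCTATGAGTAGTCTTCTTCCAAACTCGGTTCTGGATATGATCGCTGACTGCACGAGTCA",
    "GGAAGCACGGCCTAAAGTAGAAGTGTTAGCGCAAACGCTGAGATTCTTAGAGTGCATCAATGGGATAAAAGCTAAC",
    "TGACTTGCGCCTAATTAAGTCGTACAGGAGTGGGATCTGCAAGGGTGTACAGATTGACTCAGGCTAGCTGGGCCAG",
    "TCGTTTTGGCACGTAGGAATCTTGTAATTTTACGATCCAGCTGCATTCAAGACAGAATCAGCAGCCGAGCCGATTG",
)
ISOTYPES = ("S", "G", "L", "R", "K", "T", "V", "A", "N", "D", "E", "F", "H", "I")

CANONICAL_KINDS = ("canonical_island", "tandem_array")
DESIGNED_FILTER = {
    "decoy_no_integrase": "integrase",
    "decoy_excluded_integrase": "integrase",
    "decoy_fragment_in_domain": "cds",
    "decoy_fragment_in_tdna": "tdna",
    "decoy_short": "length",
    "decoy_long": "length",
    "decoy_internal_fragment": "internal",
    "decoy_wrong_side": "configuration",
    "decoy_wrong_orientation": "orientation",
}
DECOY_KINDS = tuple(DESIGNED_FILTER)
ALL_KINDS = CANONICAL_KINDS + DECOY_KINDS

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)


@dataclass
class PlantSpec:
    """One planted island (or decoy) on the synthetic replicon."""

    kind: str = "canonical_island"
    island_length: int = 10000
    crossover: int = 38  # tDNA-local crossover position, 0 < c < L
    damaged: bool = False
    side: str = "three_prime"  # five_prime plants put the fragment upstream
    tdna_strand: str = "+"
    isotype: Optional[str] = None  # default: per-template isotype; "tmRNA" allowed
    array_size: int = 1
    internal_span: Tuple[int, int] = (20, 55)  # for decoy_internal_fragment

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown plant kind {self.kind!r}")
        if self.kind == "decoy_short" and self.island_length == 10000:
            self.island_length = 1500
        if self.kind == "decoy_long" and self.island_length == 10000:
            self.island_length = 201000
        if self.kind == "tandem_array" and self.array_size < 2:
            self.array_size = 2


@dataclass
class SyntheticPlan:
    seed: int
    plants: List[PlantSpec]
    topology: str = "linear"
    rotation: int = 0
    gc: float = 0.5
    replicon_length: Optional[int] = None
    spacer: int = 1500
    replicon_id: str = "synrep1"
    organism: Organism = field(
        default_factory=lambda: Organism("Synthetica", "exemplaris", "syn1")
    )


@dataclass
class TruthIsland:
    interval: Interval
    length: int
    side: str
    damaged: bool
    subsite: str
    tandem_index: Optional[Tuple[int, int]]
    tdna_id: str


@dataclass
class TruthRecord:
    plant_index: int
    kind: str
    tdna_id: str
    designed_filter: Optional[str]
    islands: List[TruthIsland]
    fragment_intervals: List[Interval]
    host_tdna_id: Optional[str] = None


@dataclass
class TruthTable:
    replicon_id: str
    seed: int
    records: List[TruthRecord]

    @property
    def expected_islands(self) -> List[TruthIsland]:
        return [isl for rec in self.records for isl in rec.islands]


@dataclass
class GeneratedData:
    replicon: Replicon
    tdnas: List[TdnaGene]
    integrases: List[IntegraseCall]
    domains: List[DomainCall]
    truth: TruthTable


class _Builder:
    """Accumulates sequence chunks and features with global coordinates."""

    def __init__(self, rng: np.random.Generator, gc: float):
        self.rng = rng
        self.gc = gc
        self.chunks: List[str] = []
        self.pos = 0
        self.protected: List[Tuple[int, int]] = []

    def emit(self, seq: str, protect: bool = False) -> Tuple[int, int]:
        s = self.pos
        self.chunks.append(seq)
        self.pos += len(seq)
        if protect and seq:
            self.protected.append((s, self.pos))
        return s, self.pos

    def random_dna(self, n: int) -> str:
        if n <= 0:
            return ""
        p_gc = self.gc / 2
        p_at = (1 - self.gc) / 2
        return "".join(
            self.rng.choice(list("ACGT"), size=n, p=[p_at, p_gc, p_gc, p_at])
        )

    def sequence(self) -> str:
        return "".join(self.chunks)


_GUARD_N = 12  # length of the N-run flanking each planted fragment


def _n_guard() -> str:
    """Alignment barrier flanking a planted fragment.

    N matches nothing under the search scoring, so any alignment path into or
    across the run is strictly score-decreasing; the planted fragment's hit
    boundaries are therefore pinned to the planted copy exactly.  Windows
    containing an N cannot seed, so fragment edges also generate no stray
    word matches.
    """
    return "N" * _GUARD_N


def _orf(rng: np.random.Generator, n_codons: int = 200) -> str:
    codons = rng.choice(len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in codons)


def _validate(spec: PlantSpec, config: PipelineConfig, L: int) -> None:
    c = spec.crossover
    if not 0 < c < L:
        raise ValueError(f"crossover {c} outside (0, {L})")
    if spec.kind == "decoy_internal_fragment":
        a, b = spec.internal_span
        if not (0 < a < b <= L - config.damage_offset - 1):
            raise ValueError(f"internal span {spec.internal_span} not strictly internal")
        if b - a < config.min_fragment_len:
            raise ValueError("internal fragment shorter than min_fragment_len")
        return
    if spec.side == "five_prime" and spec.kind != "canonical_island":
        raise ValueError("five_prime geometry is only supported for canonical islands")
    if spec.side == "three_prime":
        flen = L - c - (config.damage_offset if spec.damaged else 0)
    else:
        flen = c
    if spec.kind == "decoy_wrong_side":
        flen = c
    elif spec.kind == "decoy_wrong_orientation":
        flen = L - c
    if flen < config.min_fragment_len:
        raise ValueError(
            f"{spec.kind}: fragment of {flen} nt is below min_fragment_len"
        )
    if flen * config.match_score < config.min_fragment_score:
        raise ValueError(f"{spec.kind}: fragment of {flen} nt cannot reach the score floor")
    if spec.island_length < flen + _PAD1 + _ORF_OVERHEAD + 90:
        raise ValueError(f"{spec.kind}: island_length {spec.island_length} too small")


class _Local:
    """Block-local assembler; coordinates are relative to the block start."""

    def __init__(self) -> None:
        self.seq: List[str] = []
        self.pos = 0
        self.feats: List[dict] = []
        self.protected: List[Tuple[int, int]] = []
        self.islands: List[dict] = []
        self.fragments: List[Tuple[int, int]] = []

    def add(self, s: str, tag: Optional[str] = None, protect: bool = False, **meta):
        st = self.pos
        self.seq.append(s)
        self.pos += len(s)
        if protect and s:
            self.protected.append((st, self.pos))
        if tag:
            self.feats.append({"tag": tag, "s": st, "e": self.pos, "strand": "+", **meta})
        return st, self.pos

    def mirror(self) -> None:
        """Reverse-complement the whole block in place (for '-'-strand genes)."""
        total = "".join(self.seq)
        B = len(total)
        self.seq = [revcomp(total)]
        flip = lambda se: (B - se[1], B - se[0])  # noqa: E731
        for f in self.feats:
            f["s"], f["e"] = B - f["e"], B - f["s"]
            f["strand"] = "-" if f["strand"] == "+" else "+"
        self.protected = [flip(p) for p in self.protected]
        self.fragments = [flip(p) for p in self.fragments]
        for isl in self.islands:
            isl["s"], isl["e"] = B - isl["e"], B - isl["s"]

    def text(self) -> str:
        return "".join(self.seq)


_ORF_CODONS = 200
_ORF_NT = 3 * _ORF_CODONS
_ORF_OVERHEAD = _ORF_NT + 6  # flanked by TAA stop codons
_PAD1 = 120


def _add_orf(loc: _Local, rng: np.random.Generator, subfamily: str = "generic",
             integron_evalue: Optional[float] = None) -> None:
    loc.add("TAA")
    s, e = loc.add(
        _orf(rng), tag="orf", subfamily=subfamily, integron_evalue=integron_evalue
    )
    loc.add("TAA")


def _add_fragment(
    loc: _Local, rng: np.random.Generator, Q: str, a: int, b: int,
    guard_left: bool = True, guard_right: bool = True,
) -> Tuple[int, int]:
    """Plant Q[a:b] on the forward strand between N-run alignment barriers."""
    if guard_left:
        loc.add(_n_guard())
    s, e = loc.add(Q[a:b], tag="frag", protect=True)
    loc.fragments.append((s, e))
    if guard_right:
        loc.add(_n_guard())
    return s, e


def _build_block(
    b: _Builder,
    spec: PlantSpec,
    template: str,
    host_template: Optional[str],
    config: PipelineConfig,
) -> _Local:
    """Assemble one plant (gene built on '+', mirrored afterwards if needed)."""
    rng = b.rng
    L = len(template)
    c = spec.crossover
    loc = _Local()
    kind = spec.kind
    damage = config.damage_offset if spec.damaged else 0

    if spec.side == "five_prime" and kind == "canonical_island":
        # upstream 5' fragment: island = [fragment start, gene start)
        isl_s = loc.pos
        _add_fragment(loc, rng, template, 0, c, guard_left=False)
        loc.add(b.random_dna(_PAD1))
        _add_orf(loc, rng)
        pad2 = spec.island_length - (loc.pos - isl_s)
        if pad2 < 0:
            raise ValueError(f"{kind}: island_length too small for contents")
        loc.add(b.random_dna(pad2))
        loc.add(template, tag="tdna", protect=True)
        loc.islands.append(
            {"s": isl_s, "e": isl_s + spec.island_length, "side": "five_prime",
             "damaged": False, "crossover": c, "tandem": None}
        )
        return loc

    # all remaining layouts put the fragment (or host gene) downstream
    loc.add(template, tag="tdna", protect=True)
    n_members = spec.array_size if kind == "tandem_array" else 1
    prev_end = loc.pos  # island/segment start: the gene's forward end
    for member in range(1, n_members + 1):
        target_end = prev_end + spec.island_length
        loc.add(b.random_dna(_PAD1))
        if kind == "decoy_no_integrase":
            pass
        elif kind == "decoy_excluded_integrase":
            label = rng.choice(["XerC", "XerD", "XerS", "XerD-like", "integron"])
            if label == "integron":
                _add_orf(loc, rng, subfamily="generic", integron_evalue=1.0e-30)
            else:
                _add_orf(loc, rng, subfamily=str(label))
        else:
            _add_orf(loc, rng)

        if kind == "decoy_fragment_in_tdna":
            assert host_template is not None
            flen = L - c
            prefix = host_template[: L - flen - _GUARD_N]
            pad2 = target_end - loc.pos - L
            if pad2 < 0:
                raise ValueError(f"{kind}: island_length too small for contents")
            loc.add(b.random_dna(pad2))
            hs, _ = loc.add(prefix, protect=True)
            loc.add(_n_guard())
            fs, fe = loc.add(template[c:], protect=True)
            loc.feats.append({"tag": "host_tdna", "s": hs, "e": fe, "strand": "+"})
            loc.fragments.append((fs, fe))
            frag_end = fe
        else:
            if kind == "decoy_internal_fragment":
                Q, a, bb = template, spec.internal_span[0], spec.internal_span[1]
            elif kind == "decoy_wrong_side":
                Q, a, bb = template, 0, c
            elif kind == "decoy_wrong_orientation":
                Q, a, bb = revcomp(template), 0, L - c
            else:  # canonical three-prime fragment, possibly damaged
                Q, a, bb = template, c, L - damage
            flen = bb - a
            pad2 = target_end - loc.pos - flen - _GUARD_N  # left guard
            if pad2 < 0:
                raise ValueError(f"{kind}: island_length too small for contents")
            loc.add(b.random_dna(pad2))
            fs, fe = _add_fragment(loc, rng, Q, a, bb)
            frag_end = fe
        assert frag_end == target_end, "island packing arithmetic is off"
        if kind in CANONICAL_KINDS:
            loc.islands.append(
                {
                    "s": prev_end,
                    "e": frag_end,
                    "side": "three_prime",
                    "damaged": spec.damaged,
                    "crossover": c,
                    "tandem": (member, n_members) if kind == "tandem_array" else None,
                }
            )
        prev_end = frag_end
    if kind == "decoy_fragment_in_domain":
        fs, fe = loc.fragments[-1]
        loc.feats.append(
            {"tag": "decoy_domain", "s": max(0, fs - 10), "e": fe + 10, "strand": "+"}
        )
    if spec.tdna_strand == "-":
        loc.mirror()
    return loc


def _verify_no_spurious_hits(
    replicon: Replicon,
    tdnas: List[TdnaGene],
    records: List[TruthRecord],
    config: PipelineConfig,
) -> bool:
    """Re-run the fragment search and demand it reproduces the designed hits.

    Every designed fragment must be recovered with exactly its planted subject
    interval, and any additional hit must be fully contained in an annotated
    tDNA (cross-hits between a host gene and the plant whose fragment it
    carries; the tDNA filter disposes of these).  Anything else -- a
    chance alignment in the background, or an alignment that crept past a
    guard -- fails verification and triggers regeneration.
    """
    from .intervals import contains

    designed: Dict[str, set] = {}
    for rec in records:
        designed.setdefault(rec.tdna_id, set()).update(
            (iv.start, iv.end) for iv in rec.fragment_intervals
        )
    L = len(replicon)
    for g in tdnas:
        want = set(designed.get(g.id, set()))
        for h in find_fragment_hits(g, replicon, config):
            key = (h.subject_interval.start, h.subject_interval.end)
            if key in want:
                want.discard(key)
                continue
            if any(
                t.id != g.id and contains(t.interval, h.subject_interval, L)
                for t in tdnas
            ):
                continue
            log.info("unexpected hit: query %s at %s", g.id, h.subject_interval)
            return False
        if want:
            log.info("designed fragments not recovered for %s: %s", g.id, want)
            return False
    return True


def generate(plan: SyntheticPlan, config: Optional[PipelineConfig] = None) -> GeneratedData:
    """Build the replicon, annotations and truth table for a plan.

    Deterministic for a given plan (same seed -> byte-identical sequence and
    truth).  Raises before emitting anything when the plan cannot be packed.
    """
    config = config or PipelineConfig()
    if len(plan.plants) > len(TEMPLATES):
        raise ValueError(
            f"at most {len(TEMPLATES)} plants per replicon (one template each)"
        )
    # template assignment: plants take templates in order; in_tdna decoys also
    # consume a host template from the tail of the registry
    host_cursor = len(TEMPLATES) - 1
    assignments: List[Tuple[str, Optional[str]]] = []
    for i, spec in enumerate(plan.plants):
        host = None
        if spec.kind == "decoy_fragment_in_tdna":
            if host_cursor <= i:
                raise ValueError("not enough templates for host genes")
            host = TEMPLATES[host_cursor]
            host_cursor -= 1
        assignments.append((TEMPLATES[i], host))
    for spec, (template, _h) in zip(plan.plants, assignments):
        _validate(spec, config, len(template))

    # In rare backgrounds the word cleaner cannot break every collision; the
    # next RNG substream then regenerates the random content (feature
    # coordinates depend only on the plan, so truth never moves).
    seq = None
    for attempt in range(8):
        rng = np.random.default_rng([plan.seed, attempt])
        b = _Builder(rng, plan.gc)
        tdnas: List[TdnaGene] = []
        integrases: List[IntegraseCall] = []
        domains: List[DomainCall] = []
        records: List[TruthRecord] = []
        counter = {"t": 0, "ig": 0, "dom": 0}

        for idx, (spec, (template, host_template)) in enumerate(
            zip(plan.plants, assignments)
        ):
            b.emit(b.random_dna(plan.spacer))
            loc = _build_block(b, spec, template, host_template, config)
            off = b.pos
            b.emit(loc.text())
            b.protected.extend((s + off, e + off) for s, e in loc.protected)
            _register(
                loc, off, spec, idx, plan, counter,
                tdnas, integrases, domains, records,
            )
        b.emit(b.random_dna(plan.spacer))

        if plan.replicon_length is not None:
            if plan.replicon_length < b.pos:
                raise ValueError(
                    f"replicon_length {plan.replicon_length} smaller than packed "
                    f"content ({b.pos} bp)"
                )
            b.emit(b.random_dna(plan.replicon_length - b.pos))

        seq = _clean_background(
            b.sequence(), b.protected,
            _collision_vocabulary(plan, assignments), config,
        )
        probe = Replicon(
            id=plan.replicon_id, sequence=seq, topology=plan.topology,
            organism=plan.organism,
        )
        if _verify_no_spurious_hits(probe, tdnas, records, config):
            break
        log.info(
            "attempt %d produced a spurious alignment; regenerating with the "
            "next substream", attempt,
        )
        seq = None
    if seq is None:
        raise RuntimeError("could not build a spurious-hit-free replicon")

    L = len(seq)
    circular = plan.topology == "circular"
    rot = plan.rotation % L if circular else 0
    if rot:
        seq = seq[rot:] + seq[:rot]
        move = lambda iv: shift(iv, -rot, L, True)  # noqa: E731
        for g in tdnas:
            g.interval = move(g.interval)
        for ig in integrases:
            ig.orf_interval = move(ig.orf_interval)
            if ig.domain_interval is not None:
                ig.domain_interval = move(ig.domain_interval)
        for d in domains:
            d.dna_interval = move(d.dna_interval)
        for rec in records:
            rec.fragment_intervals = [move(iv) for iv in rec.fragment_intervals]
            for isl in rec.islands:
                isl.interval = move(isl.interval)

    replicon = Replicon(
        id=plan.replicon_id,
        sequence=seq,
        topology=plan.topology,
        organism=plan.organism,
    )
    return GeneratedData(
        replicon=replicon,
        tdnas=tdnas,
        integrases=integrases,
        domains=domains,
        truth=TruthTable(replicon_id=plan.replicon_id, seed=plan.seed, records=records),
    )


def _truth_subsite(isotype: str, crossover: int, L: int, config: PipelineConfig) -> str:
    if isotype == "tmRNA":
        return "NA"
    lo, hi = config.subsite_a_window
    frac = crossover / L
    return "A" if lo <= frac < hi else "J"


def _register(
    loc: _Local,
    off: int,
    spec: PlantSpec,
    idx: int,
    plan: SyntheticPlan,
    counter: Dict[str, int],
    tdnas: List[TdnaGene],
    integrases: List[IntegraseCall],
    domains: List[DomainCall],
    records: List[TruthRecord],
    config: Optional[PipelineConfig] = None,
) -> None:
    """Turn a finished block into model objects and a truth record."""
    config = config or PipelineConfig()
    isotype = spec.isotype or ISOTYPES[idx % len(ISOTYPES)]
    kind_t = "tmRNA" if isotype == "tmRNA" else "tRNA"
    tdna_id = ""
    host_id = None
    for f in loc.feats:
        iv = Interval(f["s"] + off, f["e"] + off)
        if f["tag"] == "tdna":
            counter["t"] += 1
            tdna_id = f"t{counter['t']}"
            tdnas.append(
                TdnaGene(
                    id=tdna_id, replicon_id=plan.replicon_id, interval=iv,
                    strand=f["strand"], kind=kind_t, isotype=isotype,
                )
            )
        elif f["tag"] == "host_tdna":
            counter["t"] += 1
            host_id = f"t{counter['t']}h"
            host_iso = ISOTYPES[(idx + 5) % len(ISOTYPES)]
            tdnas.append(
                TdnaGene(
                    id=host_id, replicon_id=plan.replicon_id,
                    interval=iv, strand=f["strand"], kind="tRNA", isotype=host_iso,
                )
            )
        elif f["tag"] == "orf":
            counter["ig"] += 1
            if f["strand"] == "+":
                dom = Interval(iv.start + 45, iv.start + 555)
            else:
                dom = Interval(iv.end - 555, iv.end - 45)
            integrases.append(
                IntegraseCall(
                    id=f"ig{counter['ig']}", replicon_id=plan.replicon_id,
                    orf_interval=iv, strand=f["strand"],
                    subfamily=f.get("subfamily", "generic"),
                    integron_evalue=f.get("integron_evalue"),
                    domain_interval=dom,
                )
            )
            domains.append(
                DomainCall(
                    accession="PF00589", replicon_id=plan.replicon_id,
                    dna_interval=dom, strand=f["strand"], is_integrase=True,
                )
            )
        elif f["tag"] == "decoy_domain":
            domains.append(
                DomainCall(
                    accession="PF00077", replicon_id=plan.replicon_id,
                    dna_interval=iv, strand=f["strand"], is_integrase=False,
                )
            )
    islands = [
        TruthIsland(
            interval=Interval(d["s"] + off, d["e"] + off),
            length=d["e"] - d["s"],
            side=d["side"],
            damaged=d["damaged"],
            subsite=_truth_subsite(isotype, d["crossover"], len(TEMPLATES[idx]), config),
            tandem_index=d["tandem"],
            tdna_id=tdna_id,
        )
        for d in loc.islands
    ]
    records.append(
        TruthRecord(
            plant_index=idx,
            kind=spec.kind,
            tdna_id=tdna_id,
            designed_filter=DESIGNED_FILTER.get(spec.kind),
            islands=islands,
            fragment_intervals=[Interval(s + off, e + off) for s, e in loc.fragments],
            host_tdna_id=host_id,
        )
    )


def _collision_vocabulary(
    plan: SyntheticPlan, assignments: List[Tuple[str, Optional[str]]]
) -> set:
    """Integer codes of every 7-mer (both strands) of every planted gene."""
    k = PipelineConfig().word_size
    vocab: set = set()

    def add(seq: str) -> None:
        for arr in (kmer_codes(encode(seq), k), kmer_codes(encode(revcomp(seq)), k)):
            vocab.update(int(x) for x in arr[arr >= 0])

    for spec, (template, host_template) in zip(plan.plants, assignments):
        add(template)
        if host_template is not None:
            add(host_template)
    return vocab


_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _clean_background(
    seq: str,
    protected: List[Tuple[int, int]],
    vocab: set,
    config: PipelineConfig,
    max_rounds: int = 60,
) -> str:
    """Mutate background words colliding with planted-gene vocabulary.

    Every word of the finished replicon that matches a planted gene's 7-mer
    vocabulary must lie wholly inside a planted feature, so that every
    alignment seed points at a planted copy and the truth table stays exact.
    Planted bases are immutable; guard bases may be re-picked within their
    allowed (extension-blocking) character sets; background bases are free.
    Replacement values are searched deterministically, preferring ones that
    dirty no currently-clean window.
    """
    if not vocab:
        return seq
    k = config.word_size
    codes = encode(seq).astype(np.uint8)
    n = codes.shape[0]
    allowed = np.full(n, 15, dtype=np.uint8)
    for s, e in protected:
        for i in range(s, e):
            allowed[i] = 1 << codes[i]
    allowed[codes >= 4] = 0  # N barriers: never mutated, never seed
    lut = np.zeros(4 ** k, dtype=np.bool_)
    lut[np.fromiter(sorted(vocab), dtype=np.int64)] = True
    remaining = _clean_kernel(codes, allowed, lut, k, max_rounds)
    if remaining:
        # A planted-fragment/guard junction can be unfixable when every allowed
        # guard base completes a vocabulary word.  Such seeds sit right on a
        # planted fragment; the verification pass in generate() checks that
        # they support no spurious alignment.
        log.debug("%d unavoidable junction word(s) left after cleaning", remaining)
    return _DECODE[codes].tobytes().decode("ascii")


@njit(cache=True)
def _window_code(codes, w, k, pos, val):
    """Integer code of the window at w (with codes[pos]=val); -1 if it has an N."""
    code = 0
    for t in range(k):
        c = codes[w + t]
        if w + t == pos:
            c = val
        if c >= 4:
            return -1
        code = code * 4 + c
    return code


@njit(cache=True)
def _n_free(allowed, p, k):
    free = 0
    for t in range(k):
        a = allowed[p + t]
        if a & (a - 1):  # more than one bit set
            free += 1
    return free


@njit(cache=True)
def _try_fix(codes, allowed, lut, k, p, n_win):
    """Repoint one word away from the vocabulary; True on success."""
    order = (3, 2, 4, 1, 5, 0, 6)  # interior positions give the most leverage
    for strict in (True, False):
        for t in order:
            pos = p + t
            am = allowed[pos]
            if not (am & (am - 1)):
                continue  # fixed position
            cur = codes[pos]
            for dv in range(1, 4):
                val = (cur + dv) % 4
                if not (am >> val) & 1:
                    continue
                wc = _window_code(codes, p, k, pos, val)
                if wc >= 0 and lut[wc]:
                    continue  # window p itself would stay dirty
                ok = True
                if strict:
                    lo = pos - k + 1
                    if lo < 0:
                        lo = 0
                    hi = pos if pos < n_win else n_win - 1
                    for w in range(lo, hi + 1):
                        if w == p:
                            continue
                        cur_c = _window_code(codes, w, k, -1, 0)
                        new_c = _window_code(codes, w, k, pos, val)
                        if (cur_c < 0 or not lut[cur_c]) and new_c >= 0 and lut[new_c]:
                            ok = False
                            break
                if ok:
                    codes[pos] = val
                    return True
    return False


@njit(cache=True)
def _clean_kernel(codes, allowed, lut, k, max_rounds):
    n = codes.shape[0]
    n_win = n - k + 1
    n_left = 0
    for _ in range(max_rounds):
        p = 0
        while p < n_win:
            code = _window_code(codes, p, k, -1, 0)
            if code >= 0 and lut[code] and _n_free(allowed, p, k) > 0:
                if not _try_fix(codes, allowed, lut, k, p, n_win):
                    p += k  # skip past the unfixable word for this round
                    continue
            p += 1
        n_left = 0
        for p in range(n_win):
            code = _window_code(codes, p, k, -1, 0)
            if code >= 0 and lut[code] and _n_free(allowed, p, k) > 0:
                n_left += 1
        if n_left == 0:
            return 0
    return n_left


# --- truth comparison -------------------------------------------------------


@dataclass
class DecoyReport:
    plant_index: int
    kind: str
    designed_filter: str
    candidate_found: bool
    failed_filters: Tuple[str, ...]

    @property
    def rejected_exactly_at_designed(self) -> bool:
        return self.candidate_found and self.failed_filters == (self.designed_filter,)


@dataclass
class TruthComparison:
    n_expected: int
    n_called: int
    n_matched: int
    exact_endpoint_recall: float
    precision: float
    tandem_mismatches: List[str]
    decoy_reports: List[DecoyReport]

    @property
    def all_decoys_rejected_at_designed_filter(self) -> bool:
        return all(r.rejected_exactly_at_designed for r in self.decoy_reports)


def truth_compare(called, truth: TruthTable, candidates=None, replicon_length=None) -> TruthComparison:
    """Score called islands against the truth table.

    An island counts as recovered only when both endpoints match the truth
    exactly.  When *candidates* (with fully-evaluated filter traces) are
    supplied, each decoy plant is audited: its designed candidate must fail
    exactly its designed filter.
    """
    from .model import FILTER_ORDER  # local import to avoid cycles in tooling

    expected = truth.expected_islands
    exp_keys = {(t.interval.start, t.interval.end): t for t in expected}
    called_keys = [(i.interval.start, i.interval.end) for i in called]
    matched = [key for key in called_keys if key in exp_keys]
    n_matched = len(set(matched))
    recall = n_matched / len(expected) if expected else 1.0
    precision = len(matched) / len(called) if called else 1.0

    tandem_mismatches = []
    by_key = {(i.interval.start, i.interval.end): i for i in called}
    for key, t in exp_keys.items():
        isl = by_key.get(key)
        if isl is not None and isl.tandem_index != t.tandem_index:
            tandem_mismatches.append(
                f"island at {key}: tandem {isl.tandem_index} != truth {t.tandem_index}"
            )

    decoy_reports: List[DecoyReport] = []
    if candidates is not None:
        from .intervals import overlap_length

        for rec in truth.records:
            if rec.designed_filter is None:
                continue
            best = None
            best_ov = 0
            for c in candidates:
                if c.tdna.id != rec.tdna_id:
                    continue
                for fiv in rec.fragment_intervals:
                    ov = overlap_length(c.fragment.subject_interval, fiv, replicon_length)
                    if ov > best_ov:
                        best_ov = ov
                        best = c
            if best is None:
                decoy_reports.append(
                    DecoyReport(rec.plant_index, rec.kind, rec.designed_filter, False, ())
                )
                continue
            failed = tuple(
                name for name in FILTER_ORDER if best.filter_trace.get(name) == "fail"
            )
            decoy_reports.append(
                DecoyReport(rec.plant_index, rec.kind, rec.designed_filter, True, failed)
            )
    return TruthComparison(
        n_expected=len(expected),
        n_called=len(called),
        n_matched=n_matched,
        exact_endpoint_recall=recall,
        precision=precision,
        tandem_mismatches=tandem_mismatches,
        decoy_reports=decoy_reports,
    )


def plan_from_yaml(path: str) -> SyntheticPlan:
    """Load a SyntheticPlan from YAML (keys mirror the dataclass fields)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "plants" not in data or not data["plants"]:
        raise ValueError("plan must list at least one plant")
    plants = []
    for p in data["plants"]:
        if "internal_span" in p:
            p["internal_span"] = tuple(p["internal_span"])
        plants.append(PlantSpec(**p))
    org = data.get("organism", {})
    return SyntheticPlan(
        seed=int(data["seed"]),
        plants=plants,
        topology=data.get("topology", "linear"),
        rotation=int(data.get("rotation", 0)),
        gc=float(data.get("gc", 0.5)),
        replicon_length=data.get("replicon_length"),
        spacer=int(data.get("spacer", 1500)),
        replicon_id=data.get("replicon_id", "synrep1"),
        organism=Organism(
            genus=org.get("genus", "Synthetica"),
            species=org.get("species", "exemplaris"),
            strain=org.get("strain", "syn1"),
        ),
    )


def write_truth_tsv(truth: TruthTable, path: str) -> None:
    """Truth table as TSV: one row per expected island or decoy fragment."""
    import pandas as pd

    rows = []
    for rec in truth.records:
        if rec.islands:
            for isl in rec.islands:
                rows.append(
                    {
                        "plant_index": rec.plant_index,
                        "kind": rec.kind,
                        "tdna_id": isl.tdna_id,
                        "designed_filter": "",
                        "island_start": isl.interval.start,
                        "island_end": isl.interval.end,
                        "length": isl.length,
                        "side": isl.side,
                        "damaged": int(isl.damaged),
                        "subsite": isl.subsite,
                        "tandem_k": isl.tandem_index[0] if isl.tandem_index else "",
                        "tandem_n": isl.tandem_index[1] if isl.tandem_index else "",
                    }
                )
        else:
            for iv in rec.fragment_intervals:
                rows.append(
                    {
                        "plant_index": rec.plant_index,
                        "kind": rec.kind,
                        "tdna_id": rec.tdna_id,
                        "designed_filter": rec.designed_filter or "",
                        "island_start": "",
                        "island_end": "",
                        "length": "",
                        "side": "",
                        "damaged": "",
                        "subsite": "",
                        "tandem_k": "",
                        "tandem_n": "",
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_suite_plan(
    seed: int,
    tdna_strand: str = "+",
    topology: str = "linear",
    rotation: int = 0,
) -> SyntheticPlan:
    """Standard validation plan: canonical islands, a tandem array, and one
    decoy per filter class.

    Canonical crossovers probe both att subsites (A near mid-gene, J in the 3'
    third) plus the damaged-fragment and upstream-5'-fragment geometries.  On
    circular replicons the total length is padded so that even the over-long
    decoy island spans less than half the circle, keeping the shorter-arc
    candidate construction unambiguous.
    """
    plants = [
        PlantSpec(kind="canonical_island", island_length=5000, crossover=38,
                  tdna_strand=tdna_strand),
        PlantSpec(kind="canonical_island", island_length=4000, crossover=53,
                  damaged=True, tdna_strand=tdna_strand),
        PlantSpec(kind="canonical_island", island_length=4500, crossover=30,
                  side="five_prime", tdna_strand=tdna_strand),
        PlantSpec(kind="tandem_array", island_length=3000, crossover=53,
                  array_size=3, tdna_strand=tdna_strand),
    ] + [
        PlantSpec(
            kind=k,
            island_length=(
                201000 if k == "decoy_long" else 1500 if k == "decoy_short" else 4000
            ),
            crossover=45,
            tdna_strand=tdna_strand,
        )
        for k in DECOY_KINDS
    ]
    return SyntheticPlan(
        seed=seed,
        plants=plants,
        topology=topology,
        rotation=rotation,
        replicon_length=520000 if topology == "circular" else None,
    )


def length_bounds_plan(seed: int) -> SyntheticPlan:
    """Six otherwise-canonical islands probing the 2 kb / 200 kb length bounds.

    Island lengths 1.5, 2, 50, 200, 201 and 611 kb; only the length filter
    separates them, so the accepted set directly exhibits the bounds (the 611
    kb plant mimics a known over-long symbiosis island lost to this filter).
    """
    lengths = [1500, 2000, 50000, 200000, 201000, 611000]
    plants = [
        PlantSpec(kind="canonical_island", island_length=n, crossover=38)
        for n in lengths
    ]
    return SyntheticPlan(seed=seed, plants=plants)
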