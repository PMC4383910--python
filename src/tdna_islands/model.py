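"""Domain types for tDNA-targeted genomic island mapping.

The central objects mirror the biology of tyrosine-integrase site-specific
recombination at tRNA/tmRNA genes (tDNAs): an island integrates into a tDNA,
splitting it; sequences on the island regenerate the gene, leaving a displaced
fragment of the tDNA at the island's far end.  The intact gene and its
displaced fragment bracket the island at single-nucleotide resolution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import yaml

from .intervals import Interval

AA_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "SeC": "U", "Sec": "U", "Pyl": "O", "fMet": "M", "Ile2": "I",
}

XER_SUBFAMILIES = ("XerC", "XerD", "XerS", "XerD-like")
INTEGRASE_SUBFAMILIES = ("generic",) + XER_SUBFAMILIES


@dataclass
class Organism:
    genus: str = ""
    species: str = ""
    strain: str = ""


@dataclass
class Replicon:
    """One DNA molecule (chromosome, plasmid, ...) to be scanned."""

    id: str
    sequence: str
    topology: str = "linear"  # or "circular"
    organism: Organism = field(default_factory=Organism)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"replicon {self.id!r} has an empty sequence")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"replicon {self.id!r}: unknown topology {self.topology!r}")

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TdnaGene:
    """An annotated tRNA or tmRNA gene — the query whose fragments signal islands."""

    id: str
    replicon_id: str
    interval: Interval
    strand: str
    kind: str  # "tRNA" | "tmRNA"
    isotype: str  # one-letter amino-acid code, or "tmRNA"
    anticodon: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"tDNA {self.id}: bad strand {self.strand!r}")
        if self.kind not in ("tRNA", "tmRNA"):
            raise ValueError(f"tDNA {self.id}: bad kind {self.kind!r}")
        if not self.isotype:
            raise ValueError(f"tDNA {self.id}: isotype is mandatory")

    def length(self, replicon_length: Optional[int] = None) -> int:
        return self.interval.length(replicon_length)


@dataclass
class IntegraseCall:
    """A tyrosine-integrase (PF00589) hit on an ORF, with subfamily labelling."""

    id: str
    replicon_id: str
    orf_interval: Interval
    strand: str
    subfamily: str = "generic"
    integron_evalue: Optional[float] = None
    domain_interval: Optional[Interval] = None

    def __post_init__(self) -> None:
        if self.subfamily not in INTEGRASE_SUBFAMILIES:
            raise ValueError(f"integrase {self.id}: unknown subfamily {self.subfamily!r}")
        if self.integron_evalue is not None and self.integron_evalue < 0:
            raise ValueError(f"integrase {self.id}: negative E-value {self.integron_evalue}")


@dataclass
class DomainCall:
    """A Pfam-A domain hit projected onto DNA coordinates."""

    accession: str
    replicon_id: str
    dna_interval: Interval
    strand: str
    is_integrase: bool = False


@dataclass
class FragmentHit:
    """A local-alignment hit of a tDNA elsewhere on its replicon.

    ``query_span`` is in tDNA-local coordinates (0-based half-open, 5'->3' of
    the gene regardless of genomic strand).
    """

    tdna_id: str
    subject_interval: Interval
    subject_strand: str
    query_span: Tuple[int, int]
    score: float
    identities: int
    aligned_length: int = 0
    side: str = "internal"  # five_prime | three_prime | internal
    damaged: bool = False


FILTER_ORDER = (
    "integrase",
    "cds",
    "tdna",
    "length",
    "internal",
    "configuration",
    "orientation",
)


@dataclass
class CandidateIsland:
    """A tDNA-fragment interval, carrying per-filter pass/fail state."""

    tdna: TdnaGene
    fragment: FragmentHit
    island_interval: Interval
    length: int
    fragment_downstream: bool  # in tDNA-local orientation
    integrases_within: List[IntegraseCall] = field(default_factory=list)
    filter_trace: Dict[str, str] = field(default_factory=dict)
    subsite: str = "NA"  # A | J | NA

    @property
    def rejected_by(self) -> Optional[str]:
        for name in FILTER_ORDER:
            if self.filter_trace.get(name) == "fail":
                return name
        return None


@dataclass
class FilterTrace:
    """Candidates entering and rejected per filter, in cascade order."""

    entering: Dict[str, int] = field(default_factory=dict)
    rejected: Dict[str, int] = field(default_factory=dict)

    def as_rows(self) -> List[Tuple[str, int, int]]:
        return [(n, self.entering.get(n, 0), self.rejected.get(n, 0)) for n in FILTER_ORDER]


@dataclass
class IslandRecord:
    """An accepted, resolved, named island with exact endpoints."""

    name: str
    replicon_id: str
    interval: Interval
    length: int
    target_id: str
    target_isotype: str
    site_letter: str
    subsite: str
    fragment_side: str
    damaged: bool
    tandem_index: Optional[Tuple[int, int]]  # (k, n) or None
    integrase_count: int
    fragment_score: float = 0.0
    fragment_identities: int = 0
    strand: str = "+"


@dataclass
class SummaryStats:
    total_islands: int = 0
    genomes_with_island: int = 0
    mean_islands_per_positive_genome: float = 0.0
    mean_defined: bool = True
    islands_damaged: int = 0
    islands_3prime: int = 0
    islands_5prime: int = 0
    islands_A: int = 0
    islands_J: int = 0
    islands_subsite_na: int = 0
    tandem_ge2: int = 0
    tandem_ge3: int = 0


@dataclass
class PipelineConfig:
    """Every numeric threshold of the search, with its stated or chosen default.

    Attributes
    ----------
    min_len, max_len:
        Accepted island length bounds in bp (2 kb - 200 kb).
    word_size:
        Exact-match seed length for the fragment search.
    match_score, mismatch_score:
        Per-base local-alignment scores (BLASTN task defaults).
    gap_open, gap_extend:
        Affine gap model: a k-residue gap costs ``gap_open + k * gap_extend``.
    min_fragment_len, min_fragment_score:
        Reporting floors replacing a BLAST E-value cutoff.
    integron_evalue_max:
        Integrase hits against the integron-integrase profile at E-value at or
        below this are classed as integron integrases and excluded.
    damage_offset:
        Size in nt of the tolerated 3' deletion (3 bp upstream of the
        discriminator) in damaged displaced fragments.
    subsite_a_window:
        tDNA-local fractional window (lo, hi) of the fragment crossover that is
        called subsite A (anticodon-arm region); crossovers at/above hi are J.
    """

    min_len: int = 2000
    max_len: int = 200000
    word_size: int = 7
    match_score: float = 2.0
    mismatch_score: float = -3.0
    gap_open: float = 0.0
    gap_extend: float = 2.5
    min_fragment_len: int = 10
    min_fragment_score: float = 20.0
    integron_evalue_max: float = 1.2e-24
    damage_offset: int = 3
    min_peptide_len: int = 50
    subsite_a_window: Tuple[float, float] = (0.30, 0.60)
    tmrna_site_letter: str = "Z"

    def __post_init__(self) -> None:
        if not self.min_len < self.max_len:
            raise ValueError("min_len must be < max_len")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.damage_offset < 0:
            raise ValueError("damage_offset must be >= 0")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "subsite_a_window" in data:
            data["subsite_a_window"] = tuple(data["subsite_a_window"])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        data = dataclasses.asdict(self)
        data["subsite_a_window"] = list(self.subsite_a_window)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
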