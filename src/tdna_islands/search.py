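"""Seeded local alignment of tDNAs against their source replicon.

The fragment search mimics a word-seeded nucleotide BLAST: exact
``word_size``-mers shared between the gene and either strand of the replicon
seed windows, and each window is scored by an exact affine-gap local
(Smith-Waterman/Gotoh) dynamic program.  Scoring is +2/-3 with a gap of k
residues costing ``gap_open + k * gap_extend`` (default 0 + 2.5k), so all cell
values are multiples of 0.5 and float comparisons are exact.

``local_align_oracle`` provides an independent full-DP reference (via
Bio.Align.PairwiseAligner) used by the test suite to validate the seeded path.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Tuple

import numpy as np
from numba import njit

from .intervals import Interval, overlap_length
from .model import FragmentHit, PipelineConfig, Replicon, TdnaGene
from .intervals import slice_sequence

log = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A=0 C=1 G=2 T=3, anything else 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of each k-window; -1 where the window contains a non-ACGT base."""
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    m = n - k + 1
    out = np.zeros(m, dtype=np.int64)
    bad = np.zeros(m, dtype=bool)
    for t in range(k):
        col = codes[t : t + m]
        out = out * 4 + col
        bad |= col >= 4
    out[bad] = -1
    return out


@njit(cache=True)
def _gotoh_fill(q, s, match, mismatch, gap_open, gap_ext):
    """Fill local-alignment DP matrices; returns (H, E, F, best, bi, bj).

    E: best score ending in a gap in the query (subject base unpaired);
    F: best score ending in a gap in the subject.
    """
    m = q.shape[0]
    n = s.shape[0]
    neg = -1e30
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), neg)
    F = np.full((m + 1, n + 1), neg)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] - gap_open - gap_ext
            e2 = E[i, j - 1] - gap_ext
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] - gap_open - gap_ext
            f2 = F[i - 1, j] - gap_ext
            if f2 > f:
                f = f2
            F[i, j] = f
            if qi < 4 and qi == s[j - 1]:
                d = H[i - 1, j - 1] + match
            else:
                d = H[i - 1, j - 1] + mismatch
            h = d
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def _traceback(H, E, F, q, s, bi, bj, match, mismatch, gap_open, gap_ext):
    """Walk back from the best cell; returns (qstart, sstart, identities)."""
    i, j = bi, bj
    identities = 0
    state = "H"
    while True:
        if state == "H":
            h = H[i, j]
            if h == 0.0 or i == 0 or j == 0:
                break
            is_match = q[i - 1] < 4 and q[i - 1] == s[j - 1]
            d = H[i - 1, j - 1] + (match if is_match else mismatch)
            if h == d:
                if is_match:
                    identities += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            if E[i, j] == H[i, j - 1] - gap_open - gap_ext:
                j -= 1
                state = "H"
            else:
                j -= 1
        else:  # F
            if F[i, j] == H[i - 1, j] - gap_open - gap_ext:
                i -= 1
                state = "H"
            else:
                i -= 1
    return i, j, identities


class RawHit:
    """Internal alignment hit in subject-forward / query-gene-local coordinates."""

    __slots__ = ("sstart", "send", "strand", "qstart", "qend", "score", "identities")

    def __init__(self, sstart, send, strand, qstart, qend, score, identities):
        self.sstart = sstart
        self.send = send
        self.strand = strand
        self.qstart = qstart
        self.qend = qend
        self.score = score
        self.identities = identities

    def __repr__(self):  # pragma: no cover - debugging aid
        return (
            f"RawHit(s=[{self.sstart},{self.send}){self.strand} "
            f"q=[{self.qstart},{self.qend}) score={self.score})"
        )


def _align_window(qc, sc, config) -> Optional[Tuple[int, int, int, int, float, int]]:
    """Best local alignment of the full query against one subject window."""
    H, E, F, best, bi, bj = _gotoh_fill(
        qc, sc, config.match_score, config.mismatch_score, config.gap_open, config.gap_extend
    )
    if best <= 0.0:
        return None
    qs, ss, ident = _traceback(
        H, E, F, qc, sc, bi, bj,
        config.match_score, config.mismatch_score, config.gap_open, config.gap_extend,
    )
    return qs, bi, ss, bj, best, ident


def _seed_windows(q_codes: np.ndarray, s_kmers: np.ndarray, k: int, qlen: int) -> List[Tuple[int, int]]:
    """Cluster exact k-mer seed positions into candidate subject windows."""
    q_kmers = kmer_codes(q_codes, k)
    qset = np.unique(q_kmers[q_kmers >= 0])
    if qset.size == 0 or s_kmers.size == 0:
        return []
    hits = np.nonzero(np.isin(s_kmers, qset))[0]
    if hits.size == 0:
        return []
    margin = qlen + 8
    windows: List[Tuple[int, int]] = []
    start = prev = int(hits[0])
    for p in hits[1:]:
        p = int(p)
        if p - prev <= qlen:
            prev = p
        else:
            windows.append((max(0, start - margin), prev + k + margin))
            start = prev = p
    windows.append((max(0, start - margin), prev + k + margin))
    return windows


def search_sequences(
    query: str,
    subject: str,
    config: PipelineConfig,
    circular: bool = False,
) -> List[RawHit]:
    """Find local-alignment hits of *query* (both orientations) in *subject*.

    Returns non-redundant hits with subject coordinates on the forward strand
    (normalised modulo the subject length when ``circular``) and query spans in
    query-local 5'->3' coordinates.  Hits below the configured score or length
    floors are dropped.
    """
    k = config.word_size
    if len(query) < k:
        log.warning("query shorter than word_size (%d < %d); no search", len(query), k)
        return []
    L = len(subject)
    subj = subject
    if circular and L > len(query) + 2 * k:
        subj = subject + subject[: len(query) + 2 * k + 16]
    s_codes = encode(subj)
    s_kmers = kmer_codes(s_codes, k)

    raw: List[RawHit] = []
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        qc = encode(qseq)
        for ws, we in _seed_windows(qc, s_kmers, k, len(qseq)):
            we = min(we, len(subj))
            res = _align_window(qc, s_codes[ws:we], config)
            if res is None:
                continue
            qs, qe, ss, se, score, ident = res
            if score < config.min_fragment_score:
                continue
            if se - ss < config.min_fragment_len or qe - qs < config.min_fragment_len:
                continue
            if strand == "-":
                qs, qe = len(qseq) - qe, len(qseq) - qs
            raw.append(RawHit(ws + ss, ws + se, strand, qs, qe, score, ident))

    return _dedupe(raw, L, circular)


def _normalise(hit: RawHit, L: int, circular: bool) -> Optional[Interval]:
    s, e = hit.sstart, hit.send
    if not circular:
        if s >= L:  # entirely outside (cannot happen without extension)
            return None
        return Interval(s, min(e, L))
    if s >= L:  # duplicate of a hit found in the first copy
        return None
    e_mod = e % L if e % L != 0 else L
    if e <= L:
        return Interval(s, e)
    return Interval(s, e_mod)  # wraps: s > e_mod


def _dedupe(raw: List[RawHit], L: int, circular: bool) -> List[RawHit]:
    """Drop duplicates/near-duplicates: >50% overlap keeps the higher score."""
    hits: List[Tuple[Interval, RawHit]] = []
    for h in raw:
        iv = _normalise(h, L, circular)
        if iv is None:
            continue
        h.sstart, h.send = iv.start, iv.end
        hits.append((iv, h))
    hits.sort(key=lambda t: (-t[1].score, t[0].start, t[0].end, t[1].strand))
    kept: List[Tuple[Interval, RawHit]] = []
    for iv, h in hits:
        redundant = False
        for kiv, _kh in kept:
            ov = overlap_length(iv, kiv, L)
            shorter = min(iv.length(L), kiv.length(L))
            if shorter > 0 and ov / shorter > 0.5:
                redundant = True
                break
        if not redundant:
            kept.append((iv, h))
    kept.sort(key=lambda t: (t[0].start, t[0].end, t[1].strand))
    return [h for _iv, h in kept]


def _mask_interval(sequence: str, iv: Interval) -> str:
    chars = list(sequence)
    for s, e in iv.segments(len(sequence)):
        chars[s:e] = "N" * (e - s)
    return "".join(chars)


def find_fragment_hits(
    tdna: TdnaGene, replicon: Replicon, config: PipelineConfig
) -> List[FragmentHit]:
    """All non-self local hits of a tDNA against its source replicon.

    The gene's own locus is masked before searching, so the trivial self-hit is
    never produced and nearby fragments are still found.  ``subject_strand`` is
    the genomic strand carrying the fragment in gene orientation: '+' when the
    forward strand reads 5'->3' like the gene-oriented query.
    """
    gene_seq = slice_sequence(replicon.sequence, tdna.interval)
    if tdna.strand == "-":
        gene_seq = revcomp(gene_seq)
    if len(gene_seq) < config.word_size:
        log.warning("tDNA %s shorter than word_size; skipping", tdna.id)
        return []
    masked = _mask_interval(replicon.sequence, tdna.interval)
    out: List[FragmentHit] = []
    for h in search_sequences(gene_seq, masked, config, circular=replicon.circular):
        # A '+' search hit means the forward genomic strand carries the
        # gene-oriented sequence, so the hit strand IS the fragment's genomic
        # strand, independent of which strand the gene itself sits on.
        out.append(
            FragmentHit(
                tdna_id=tdna.id,
                subject_interval=Interval(h.sstart, h.send),
                subject_strand=h.strand,
                query_span=(h.qstart, h.qend),
                score=h.score,
                identities=h.identities,
                aligned_length=h.qend - h.qstart,
            )
        )
    return out


def classify_fragment_side(
    hit: FragmentHit, tdna: TdnaGene, config: PipelineConfig, tdna_length: Optional[int] = None
) -> FragmentHit:
    """Set ``side`` and ``damaged`` from the hit's query span.

    A fragment touching the gene's 5' terminus is five_prime; one reaching to
    within ``damage_offset`` nt of the 3' terminus is three_prime (damaged when
    it stops short of the true end, the tolerated deletion 3 bp upstream of the
    discriminator); anything else is internal.
    """
    L = tdna_length if tdna_length is not None else tdna.interval.length()
    qs, qe = hit.query_span
    if qs == 0:
        hit.side = "five_prime"
        hit.damaged = False
    elif qe >= L - config.damage_offset:
        hit.side = "three_prime"
        hit.damaged = qe < L
    else:
        hit.side = "internal"
        hit.damaged = False
    return hit


def local_align_oracle(
    a: str, b: str, config: PipelineConfig
) -> Tuple[float, Tuple[int, int], Tuple[int, int]]:
    """Exact maximal local alignment score by full dynamic programming.

    Independent reference for the seeded search, delegated to
    Bio.Align.PairwiseAligner with the same affine gap model (a k-gap costs
    ``gap_open + k * gap_extend``).  Returns (score, a_span, b_span); empty
    inputs or an all-negative matrix give (0.0, (0, 0), (0, 0)).
    """
    from Bio import Align

    if not a or not b:
        return 0.0, (0, 0), (0, 0)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = config.match_score
    aligner.mismatch_score = config.mismatch_score
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    score = float(aligner.score(a, b))
    if score <= 0.0:
        return 0.0, (0, 0), (0, 0)
    aln = aligner.align(a, b)[0]
    a_blocks, b_blocks = aln.aligned
    a_span = (int(a_blocks[0][0]), int(a_blocks[-1][1]))
    b_span = (int(b_blocks[0][0]), int(b_blocks[-1][1]))
    return score, a_span, b_span
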