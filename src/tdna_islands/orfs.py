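"""Six-frame stop-to-stop ORF extraction and integrase admission.

Island integrases are tyrosine recombinases (Pfam PF00589) found among
six-frame translations, amino-acid sequences extending from stop codon to
stop codon.  Two subclasses are not island integrases and are excluded before
filtering: Xer proteins (host dimer-resolvases acting at dif sites, labelled
XerC/XerD/XerS/XerD-like) and integron integrases (a hit against the
integron-integrase profile at E-value <= 1.2e-24 marks a call as
integron-like).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

from .intervals import Interval
from .model import IntegraseCall, PipelineConfig, Replicon
from .search import revcomp

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})  # translation table 11


@dataclass(frozen=True)
class OrfRecord:
    """A maximal stop-free run in one reading frame (forward DNA coordinates)."""

    interval: Interval
    strand: str
    frame: int  # 1..3 within strand
    peptide_length: int


def _scan_frame(seq: str, offset: int, min_peptide_len: int):
    """Yield (codon_start_index, n_codons) runs of stop-free codons in one frame."""
    n = (len(seq) - offset) // 3
    run_start = 0
    run_len = 0
    for c in range(n):
        codon = seq[offset + 3 * c : offset + 3 * c + 3]
        if codon in STOP_CODONS:
            if run_len >= min_peptide_len:
                yield run_start, run_len
            run_start = c + 1
            run_len = 0
        else:
            run_len += 1
    if run_len >= min_peptide_len:
        yield run_start, run_len


def six_frame_orfs(replicon: Replicon, min_peptide_len: int = 50) -> List[OrfRecord]:
    """Every maximal stop-free run in each of the six frames.

    Sequence ends bound runs on linear replicons; on circular replicons each
    frame is scanned across the origin (runs may wrap, capped at one full
    turn).  Codons containing N count as sense codons.
    """
    min_peptide_len = max(1, min_peptide_len)
    L = len(replicon)
    out: List[OrfRecord] = []
    for strand in "+-":
        seq = replicon.sequence if strand == "+" else revcomp(replicon.sequence)
        scan_seq = seq + seq[: max(0, L - 1)] if replicon.circular else seq
        for offset in range(3):
            frame = offset + 1
            seen = set()
            for run_start, run_len in _scan_frame(scan_seq, offset, min_peptide_len):
                s = offset + 3 * run_start
                if replicon.circular:
                    if s >= L:  # duplicate of a run already seen in the first copy
                        continue
                    cap = (L // 3) * 3
                    nt = min(3 * run_len, cap)
                    if nt >= L:  # a stop-free full circle: cap below one turn
                        nt = cap - 3
                else:
                    nt = 3 * run_len
                if nt < 3 * min_peptide_len:
                    continue
                e = s + nt
                # map strand-local to forward coordinates
                if strand == "+":
                    iv_s, iv_e = s, e
                else:
                    iv_s, iv_e = L - e, L - s
                if replicon.circular:
                    iv_s %= L
                    iv_e = iv_e % L or L
                key = (iv_s, iv_e)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    OrfRecord(
                        interval=Interval(iv_s, iv_e),
                        strand=strand,
                        frame=frame,
                        peptide_length=nt // 3,
                    )
                )
    out.sort(key=lambda o: (o.interval.start, o.interval.end, o.strand, o.frame))
    return out


def admit_integrases(
    calls: List[IntegraseCall], config: PipelineConfig
) -> List[IntegraseCall]:
    """Keep island-integrase candidates; exclude Xer and integron subclasses.

    A call is admitted when its subfamily is 'generic' and it either has no
    integron-profile E-value or that E-value is above the exclusion threshold
    (a stronger, smaller E-value means more integron-like).  Idempotent and
    order-preserving; exclusions are logged with a reason code.
    """
    admitted: List[IntegraseCall] = []
    for call in calls:
        if call.integron_evalue is not None and call.integron_evalue < 0:
            raise ValueError(f"integrase {call.id}: negative E-value")
        if call.subfamily != "generic":
            log.info("exclude\t%s\treason=xer_subfamily:%s", call.id, call.subfamily)
            continue
        if (
            call.integron_evalue is not None
            and call.integron_evalue <= config.integron_evalue_max
        ):
            log.info("exclude\t%s\treason=integron_evalue:%g", call.id, call.integron_evalue)
            continue
        admitted.append(call)
    return admitted
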