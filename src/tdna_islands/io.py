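"""Readers and writers for the pipeline's on-disk formats.

All disk coordinates are 1-based inclusive (GFF3/BLAST convention); internal
coordinates are 0-based half-open.  Features wrapping the origin of a circular
replicon are written as two segment lines sharing one ID and merged back into
a single wrapping interval on reading, so feature I/O round-trips exactly.

FASTA headers may carry ``key=value`` tags (topology, genus, species, strain),
e.g. ``>chr1 topology=circular genus=Escherichia species=coli strain=Sakai``.
This tag dialect, and the optional TSV feature table, are inventions of this
package, documented here and in the methods note.
"""

from __future__ import annotations

import logging
import os
import re
from typing import Dict, List, Optional, Tuple

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import Interval, slice_sequence
from .model import (
    DomainCall,
    IntegraseCall,
    IslandRecord,
    Organism,
    Replicon,
    SummaryStats,
    TdnaGene,
)

log = logging.getLogger(__name__)

_VALID = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


def read_fasta(path: str) -> List[Replicon]:
    """Read replicons from FASTA; header tags set topology and organism.

    Sequences are uppercased and non-ACGTN characters mapped to N with a
    warning.  Duplicate record ids and empty files are format errors.
    """
    replicons: List[Replicon] = []
    seen = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA record id {rec.id!r}")
        seen.add(rec.id)
        tags = dict(
            t.split("=", 1) for t in rec.description.split()[1:] if "=" in t
        )
        seq = str(rec.seq).upper()
        n_bad = len(_VALID.findall(seq))
        if n_bad:
            log.warning(
                "replicon %s: %d non-ACGTN characters mapped to N", rec.id, n_bad
            )
            seq = _VALID.sub("N", seq)
        replicons.append(
            Replicon(
                id=rec.id,
                sequence=seq,
                topology=tags.get("topology", "linear"),
                organism=Organism(
                    genus=tags.get("genus", ""),
                    species=tags.get("species", ""),
                    strain=tags.get("strain", ""),
                ),
            )
        )
    if not replicons:
        raise FormatError(f"no FASTA records in {path}")
    return replicons


def write_fasta(replicons: List[Replicon], path: str) -> None:
    records = []
    for r in replicons:
        desc = f"topology={r.topology}"
        if r.organism.genus:
            desc += f" genus={r.organism.genus.replace(' ', '_')}"
        if r.organism.species:
            desc += f" species={r.organism.species}"
        if r.organism.strain:
            desc += f" strain={r.organism.strain}"
        records.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(records, path, "fasta")


# --- feature I/O ------------------------------------------------------------

TDNA_TYPES = ("tRNA", "tmRNA")
INTEGRASE_TYPE = "integrase_CDS"
DOMAIN_TYPE = "protein_match"


def _merge_parts(
    parts: List[Tuple[int, int]], replicon: Replicon, what: str
) -> Interval:
    """Combine 0-based half-open segments of one feature into one interval."""
    L = len(replicon)
    if len(parts) == 1:
        s, e = parts[0]
        return Interval(s, e)
    if len(parts) == 2 and replicon.circular:
        parts = sorted(parts)
        (s0, e0), (s1, e1) = parts
        if s0 == 0 and e1 == L:
            return Interval(s1, e0)
    raise FormatError(f"{what}: cannot merge segments {parts} on {replicon.id}")


def _check_bounds(start1: int, end1: int, replicon: Replicon, what: str) -> None:
    if start1 < 1 or end1 > len(replicon) or start1 > end1:
        raise FormatError(
            f"{what}: coordinates {start1}..{end1} out of bounds for "
            f"{replicon.id} (length {len(replicon)})"
        )


def read_features(
    path: str, replicons: List[Replicon]
) -> Tuple[List[TdnaGene], List[IntegraseCall], List[DomainCall]]:
    """Read tDNA, integrase and domain annotations (GFF3 or TSV dialect)."""
    if path.endswith((".tsv", ".txt")):
        return _read_features_tsv(path, replicons)
    return _read_features_gff3(path, replicons)


def _first(attrs, key: str) -> Optional[str]:
    vals = attrs.get(key)
    return vals[0] if vals else None


def _read_features_gff3(path, replicons):
    by_id: Dict[str, Replicon] = {r.id: r for r in replicons}
    with open(path) as fh:
        text = fh.read()
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return [], [], []
    # group rows by (type, ID) so two-segment wrapping features merge
    grouped: Dict[Tuple[str, str], List] = {}
    order: List[Tuple[str, str]] = []
    unknown = set()
    for feat in db.all_features():
        if feat.seqid not in by_id:
            unknown.add(feat.seqid)
            continue
        fid = _first(feat.attributes, "ID") or f"{feat.featuretype}:{feat.seqid}:{feat.start}"
        fid = fid.split("_gffutils_autoincrement")[0]
        key = (feat.featuretype, fid)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(feat)
    if unknown:
        raise FormatError(
            f"features reference unknown replicons: {sorted(unknown)}"
        )
    tdnas: List[TdnaGene] = []
    integrases: List[IntegraseCall] = []
    domains: List[DomainCall] = []
    for ftype, fid in order:
        feats = grouped[(ftype, fid)]
        rep = by_id[feats[0].seqid]
        parts = []
        for f in feats:
            _check_bounds(f.start, f.end, rep, f"{ftype} {fid}")
            parts.append((f.start - 1, f.end))
        iv = _merge_parts(parts, rep, f"{ftype} {fid}")
        f0 = feats[0]
        attrs = f0.attributes
        if ftype in TDNA_TYPES:
            isotype = _first(attrs, "isotype")
            if not isotype:
                raise FormatError(f"tDNA {fid}: missing mandatory isotype attribute")
            gene = TdnaGene(
                id=fid,
                replicon_id=rep.id,
                interval=iv,
                strand=f0.strand,
                kind=ftype,
                isotype=isotype,
                anticodon=_first(attrs, "anticodon") or "",
            )
            glen = gene.length(len(rep))
            if gene.kind == "tRNA" and not 60 <= glen <= 120:
                log.warning("tDNA %s has unusual length %d nt", fid, glen)
            tdnas.append(gene)
        elif ftype == INTEGRASE_TYPE:
            ev = _first(attrs, "integron_evalue")
            ds, de = _first(attrs, "domain_start"), _first(attrs, "domain_end")
            dom_iv = None
            if ds and de:
                _check_bounds(int(ds), int(de), rep, f"integrase {fid} domain")
                dom_iv = Interval(int(ds) - 1, int(de))
            integrases.append(
                IntegraseCall(
                    id=fid,
                    replicon_id=rep.id,
                    orf_interval=iv,
                    strand=f0.strand,
                    subfamily=_first(attrs, "subfamily") or "generic",
                    integron_evalue=float(ev) if ev else None,
                    domain_interval=dom_iv,
                )
            )
        elif ftype == DOMAIN_TYPE:
            domains.append(
                DomainCall(
                    accession=_first(attrs, "accession") or fid,
                    replicon_id=rep.id,
                    dna_interval=iv,
                    strand=f0.strand,
                    is_integrase=(_first(attrs, "is_integrase") or "0") in ("1", "true", "True"),
                )
            )
        else:
            log.warning("ignoring feature of type %s", ftype)
    return tdnas, integrases, domains


def _read_features_tsv(path, replicons):
    """TSV dialect: replicon_id, feature_type, id, start, end, strand, attributes.

    Coordinates 1-based inclusive; attributes is a ';'-separated key=value
    string.  Wrapping features use two rows with the same id.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    lines = ["##gff-version 3"]
    for _, row in df.iterrows():
        attrs = f"ID={row['id']}"
        if row.get("attributes"):
            attrs += ";" + row["attributes"]
        lines.append(
            "\t".join(
                [
                    row["replicon_id"],
                    "tdna_islands",
                    row["feature_type"],
                    row["start"],
                    row["end"],
                    ".",
                    row["strand"],
                    ".",
                    attrs,
                ]
            )
        )
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
        fh.write("\n".join(lines) + "\n")
        tmp = fh.name
    try:
        return _read_features_gff3(tmp, replicons)
    finally:
        os.unlink(tmp)


def _gff3_escape(val: str) -> str:
    return val.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def _feature_lines(seqid: str, ftype: str, iv: Interval, strand: str,
                   attrs: Dict[str, str], L: int) -> List[str]:
    attr_s = ";".join(f"{k}={_gff3_escape(str(v))}" for k, v in attrs.items() if v != "")
    lines = []
    for s, e in iv.segments(L):
        lines.append(
            "\t".join([seqid, "tdna_islands", ftype, str(s + 1), str(e), ".", strand, ".", attr_s])
        )
    return lines


def write_features(
    path: str,
    replicons: List[Replicon],
    tdnas: List[TdnaGene],
    integrases: List[IntegraseCall],
    domains: List[DomainCall],
) -> None:
    """Write annotations to the GFF3 dialect read by :func:`read_features`."""
    by_id = {r.id: r for r in replicons}
    lines = ["##gff-version 3"]
    for r in replicons:
        lines.append(f"##sequence-region {r.id} 1 {len(r)}")
    for g in tdnas:
        rep = by_id[g.replicon_id]
        lines += _feature_lines(
            g.replicon_id, g.kind, g.interval, g.strand,
            {"ID": g.id, "isotype": g.isotype, "anticodon": g.anticodon}, len(rep),
        )
    for ig in integrases:
        rep = by_id[ig.replicon_id]
        attrs = {"ID": ig.id, "subfamily": ig.subfamily}
        if ig.integron_evalue is not None:
            attrs["integron_evalue"] = repr(ig.integron_evalue)
        if ig.domain_interval is not None:
            attrs["domain_start"] = str(ig.domain_interval.start + 1)
            attrs["domain_end"] = str(ig.domain_interval.end)
        lines += _feature_lines(
            ig.replicon_id, INTEGRASE_TYPE, ig.orf_interval, ig.strand, attrs, len(rep)
        )
    for i, dom in enumerate(domains):
        rep = by_id[dom.replicon_id]
        lines += _feature_lines(
            dom.replicon_id, DOMAIN_TYPE, dom.dna_interval, dom.strand,
            {"ID": f"dom{i}", "accession": dom.accession,
             "is_integrase": "1" if dom.is_integrase else "0"}, len(rep),
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# --- island output ----------------------------------------------------------

def write_outputs(
    islands: List[IslandRecord],
    replicons: List[Replicon],
    outdir: str,
    summary: Optional[SummaryStats] = None,
) -> None:
    """Emit islands.gff3, islands.fna and summary.tsv into *outdir*.

    Valid (headered, empty) files are produced when no islands were found.
    """
    os.makedirs(outdir, exist_ok=True)
    by_id = {r.id: r for r in replicons}
    lines = ["##gff-version 3"]
    fasta_records = []
    ordered = sorted(islands, key=lambda i: (i.replicon_id, i.interval.start, i.name))
    for isl in ordered:
        rep = by_id[isl.replicon_id]
        attrs = {
            "ID": isl.name,
            "Name": isl.name,
            "target": isl.target_id,
            "isotype": isl.target_isotype,
            "site_letter": isl.site_letter,
            "subsite": isl.subsite,
            "fragment_side": isl.fragment_side,
            "damaged": "1" if isl.damaged else "0",
            "integrase_count": str(isl.integrase_count),
            "length": str(isl.length),
            "fragment_score": repr(isl.fragment_score),
            "fragment_identities": str(isl.fragment_identities),
        }
        if isl.tandem_index is not None:
            attrs["tandem_index"] = f"{isl.tandem_index[0]}_of_{isl.tandem_index[1]}"
        lines += _feature_lines(
            isl.replicon_id, "genomic_island", isl.interval, isl.strand, attrs, len(rep)
        )
        fasta_records.append(
            SeqRecord(
                Seq(slice_sequence(rep.sequence, isl.interval)),
                id=isl.name,
                description=f"replicon={isl.replicon_id} length={isl.length}",
            )
        )
    with open(os.path.join(outdir, "islands.gff3"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    SeqIO.write(fasta_records, os.path.join(outdir, "islands.fna"), "fasta")
    if summary is None:
        summary = SummaryStats(total_islands=len(islands))
    rows = [
        ("Islands", str(summary.total_islands)),
        ("Genomes with at least one island", str(summary.genomes_with_island)),
        ("Islands per genome with at least one (mean)",
         f"{summary.mean_islands_per_positive_genome:.2f}"),
        ("Islands with damage", str(summary.islands_damaged)),
        ("Islands with 3' tDNA fragment", str(summary.islands_3prime)),
        ("Islands with 5' tDNA fragment", str(summary.islands_5prime)),
        ("Islands with subsite A", str(summary.islands_A)),
        ("Islands with subsite J", str(summary.islands_J)),
        ("Islands with subsite NA", str(summary.islands_subsite_na)),
        ("Tandems >= 2", str(summary.tandem_ge2)),
        ("Tandems >= 3", str(summary.tandem_ge3)),
    ]
    pd.DataFrame(rows, columns=["group", "count"]).to_csv(
        os.path.join(outdir, "summary.tsv"), sep="\t", index=False
    )


def read_islands(path: str, replicons: List[Replicon]) -> List[IslandRecord]:
    """Re-read an islands.gff3; inverse of the island part of write_outputs."""
    by_id = {r.id: r for r in replicons}
    grouped: Dict[str, List] = {}
    order: List[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if cols[2] != "genomic_island":
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            name = attrs["ID"]
            if name not in grouped:
                grouped[name] = []
                order.append(name)
            grouped[name].append((cols, attrs))
    out: List[IslandRecord] = []
    for name in order:
        rows = grouped[name]
        cols0, attrs = rows[0]
        rep = by_id[cols0[0]]
        parts = [(int(c[3]) - 1, int(c[4])) for c, _ in rows]
        iv = _merge_parts(parts, rep, f"island {name}")
        ti = attrs.get("tandem_index")
        tandem = None
        if ti:
            k, _, n = ti.partition("_of_")
            tandem = (int(k), int(n))
        out.append(
            IslandRecord(
                name=name,
                replicon_id=cols0[0],
                interval=iv,
                length=int(attrs["length"]),
                target_id=attrs["target"],
                target_isotype=attrs["isotype"],
                site_letter=attrs["site_letter"],
                subsite=attrs["subsite"],
                fragment_side=attrs["fragment_side"],
                damaged=attrs["damaged"] == "1",
                tandem_index=tandem,
                integrase_count=int(attrs["integrase_count"]),
                fragment_score=float(attrs.get("fragment_score", 0) or 0),
                fragment_identities=int(attrs.get("fragment_identities", 0) or 0),
                strand=cols0[6],
            )
        )
    return out
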