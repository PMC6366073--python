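"""Genome architecture statistics.

Computes contig-level gene-architecture summaries for a draft genome with
very low gene density: contig selection above a size cutoff, exon/intron
length statistics from transcript-to-genome gene models, coding fraction,
and splice-boundary classification. Euglenid genomes carry, besides
canonical GT..AG spliceosomal introns, introns with only one or neither
boundary canonical; boundaries are classified as conventional (GT donor
and AG acceptor), intermediate (exactly one canonical boundary) or
nonconventional (neither).

Coordinates are 0-based half-open internally and converted losslessly from
the 1-based closed GFF3 convention.
"""

from __future__ import annotations

import json
import logging
import statistics
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DEFAULT_MIN_CONTIG = 10_000  # retained iff strictly longer
CANONICAL_DONOR = "GT"
CANONICAL_ACCEPTOR = "AG"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Contig:
    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"contig {self.id}: non-positive length")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"contig {self.id}: sequence/length mismatch")


class ContigSet:
    def __init__(self, contigs: list[Contig]):
        self.contigs = {c.id: c for c in contigs}
        if len(self.contigs) != len(contigs):
            raise ValueError("duplicate contig ids")

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs.values())

    def __getitem__(self, cid: str) -> Contig:
        return self.contigs[cid]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ContigSet":
        contigs = [
            Contig(rec.id, len(rec.seq), str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(contigs)


@dataclass
class GeneModel:
    """Exon structure of one transcript aligned to a contig.

    Exons are 0-based half-open intervals, sorted, non-overlapping;
    introns are the gaps between consecutive exons.
    """
    transcript_id: str
    contig_id: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            if s2 == e1:
                raise ValueError(f"{self.transcript_id}: zero-length intron")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon")

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    @property
    def intron_intervals(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class Intron:
    transcript_id: str
    contig_id: str
    strand: str
    start: int
    end: int
    donor: str | None = None     # first two intronic bases, mRNA sense
    acceptor: str | None = None  # last two intronic bases, mRNA sense

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# GFF3 IO
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read transcript-to-genome alignments: exon features grouped by their
    Parent (or transcript_id) attribute."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        parents = feat.attributes.get("Parent") or \
            feat.attributes.get("transcript_id") or [feat.id]
        for tid in parents:
            g = grouped.setdefault(tid, {"contig": feat.seqid,
                                         "strand": feat.strand, "exons": []})
            if g["contig"] != feat.seqid or g["strand"] != feat.strand:
                raise ValueError(f"transcript {tid}: exons on mixed "
                                 "contigs/strands")
            # GFF3 is 1-based closed; internal is 0-based half-open
            g["exons"].append((feat.start - 1, feat.end))
    return [
        GeneModel(tid, g["contig"], g["strand"], g["exons"])
        for tid, g in sorted(grouped.items())
    ]


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s0, e0 = m.span
            fh.write(f"{m.contig_id}\tegmosaic\tmRNA\t{s0 + 1}\t{e0}\t.\t"
                     f"{m.strand}\t.\tID={m.transcript_id}\n")
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(f"{m.contig_id}\tegmosaic\texon\t{s + 1}\t{e}\t.\t"
                         f"{m.strand}\t.\tID={m.transcript_id}.exon{i};"
                         f"Parent={m.transcript_id}\n")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def select_contigs(contigs: ContigSet,
                   min_len: int = DEFAULT_MIN_CONTIG) -> ContigSet:
    """Contigs strictly longer than ``min_len`` bp."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = ContigSet([c for c in contigs if c.length > min_len])
    logger.info("selected %d/%d contigs > %d bp (%d bp total)",
                len(kept), len(contigs), min_len, kept.total_length)
    return kept


def derive_introns(models: list[GeneModel],
                   contigs: ContigSet) -> list[Intron]:
    """One intron per adjacent exon pair, with boundary dinucleotides read
    from the contig sequence (reverse-complemented on the minus strand)
    when sequence is available."""
    introns: list[Intron] = []
    for m in models:
        contig = contigs[m.contig_id]
        if m.span[1] > contig.length or m.span[0] < 0:
            raise ValueError(f"model {m.transcript_id} exceeds bounds of "
                             f"contig {m.contig_id}")
        for start, end in m.intron_intervals:
            donor = acceptor = None
            if contig.sequence is not None and end - start >= 4:
                seq = contig.sequence[start:end]
                if m.strand == "+":
                    donor, acceptor = seq[:2], seq[-2:]
                else:
                    rc = str(Seq(seq).reverse_complement())
                    donor, acceptor = rc[:2], rc[-2:]
            introns.append(Intron(m.transcript_id, m.contig_id, m.strand,
                                  start, end, donor, acceptor))
    return introns


def classify_splice(donor: str, acceptor: str, *,
                    gc_ag_conventional: bool = False) -> str:
    """Splice-boundary class from donor/acceptor dinucleotides.

    conventional: GT donor and AG acceptor (optionally also GC..AG);
    intermediate: exactly one boundary canonical; nonconventional:
    neither. A boundary containing N is 'ambiguous' and excluded from
    percentage denominators.
    """
    donor, acceptor = donor.upper(), acceptor.upper()
    for dn in (donor, acceptor):
        if len(dn) != 2 or any(b not in "ACGTN" for b in dn):
            raise ValueError(f"bad dinucleotide {dn!r}")
    if "N" in donor or "N" in acceptor:
        logger.warning("ambiguous splice boundary %s..%s", donor, acceptor)
        return "ambiguous"
    donor_ok = donor == CANONICAL_DONOR or \
        (gc_ag_conventional and donor == "GC")
    acceptor_ok = acceptor == CANONICAL_ACCEPTOR
    if donor_ok and acceptor_ok:
        return "conventional"
    if donor_ok or acceptor_ok:
        return "intermediate"
    return "nonconventional"


@dataclass
class ArchitectureStats:
    """Architecture summary over the selected contigs (means to 2 decimals,
    percentages to 1)."""
    n_contigs: int
    total_contig_bases: int
    n_contigs_with_cds: int
    pct_contigs_with_cds: float
    n_cds: int
    total_cds_length: int
    mean_cds_length: float
    n_exons: int
    mean_exon_length: float
    median_exon_length: float
    total_exon_length: int
    exons_per_cds: float
    n_introns: int
    mean_intron_length: float
    median_intron_length: float
    total_intron_length: int
    introns_per_cds: float
    splice_counts: dict[str, int]
    splice_percentages: dict[str, float]
    pct_nucleotides_in_cds: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def compute_stats(models: list[GeneModel], contigs: ContigSet,
                  min_contig: int = DEFAULT_MIN_CONTIG, *,
                  gc_ag_conventional: bool = False) -> ArchitectureStats:
    """Full architecture summary: contig selection, per-CDS exon/intron
    statistics, splice-class tallies and coding fraction."""
    selected = select_contigs(contigs, min_contig)
    models = [m for m in models if m.contig_id in selected.contigs]

    exon_lengths = [l for m in models for l in m.exon_lengths]
    introns = derive_introns(models, selected)
    intron_lengths = [i.length for i in introns]

    splice_counts = {"conventional": 0, "intermediate": 0,
                     "nonconventional": 0, "ambiguous": 0}
    for i in introns:
        if i.donor is None:
            continue
        splice_counts[classify_splice(
            i.donor, i.acceptor, gc_ag_conventional=gc_ag_conventional)] += 1
    n_classified = sum(v for k, v in splice_counts.items() if k != "ambiguous")
    splice_pct = {
        k: round(100 * v / n_classified, 1) if n_classified else 0.0
        for k, v in splice_counts.items() if k != "ambiguous"
    }

    n_cds = len(models)
    cds_lengths = [sum(m.exon_lengths) for m in models]
    contigs_with_cds = {m.contig_id for m in models}
    total_bases = selected.total_length

    def mean2(xs):
        return round(sum(xs) / len(xs), 2) if xs else 0.0

    return ArchitectureStats(
        n_contigs=len(selected),
        total_contig_bases=total_bases,
        n_contigs_with_cds=len(contigs_with_cds),
        pct_contigs_with_cds=round(100 * len(contigs_with_cds) / len(selected), 1)
        if len(selected) else 0.0,
        n_cds=n_cds,
        total_cds_length=sum(cds_lengths),
        mean_cds_length=mean2(cds_lengths),
        n_exons=len(exon_lengths),
        mean_exon_length=mean2(exon_lengths),
        median_exon_length=float(statistics.median(exon_lengths))
        if exon_lengths else 0.0,
        total_exon_length=sum(exon_lengths),
        exons_per_cds=round(len(exon_lengths) / n_cds, 2) if n_cds else 0.0,
        n_introns=len(intron_lengths),
        mean_intron_length=mean2(intron_lengths),
        median_intron_length=float(statistics.median(intron_lengths))
        if intron_lengths else 0.0,
        total_intron_length=sum(intron_lengths),
        introns_per_cds=round(len(intron_lengths) / n_cds, 2) if n_cds else 0.0,
        splice_counts=splice_counts,
        splice_percentages=splice_pct,
        pct_nucleotides_in_cds=round(100 * sum(exon_lengths) / total_bases, 2)
        if total_bases else 0.0,
    )
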