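"""Gene-model validation, functional/pseudogene classification, and tandem
naming for chalcone-synthase-style genes.

The canonical CHS architecture is two exons separated by one intron: a
variable first exon of 37-64 codons (start codon included) and a conserved
second exon of ~340 codons that carries both the family signature (a
catalytic-cysteine-containing motif) and the active-site motif. A candidate
is *functional* when it has that architecture with an intact ORF and both
motifs; *pseudogene* when the ORF is disrupted (missing start, internal
stop, or frameshift) but the family signature is still recognizable in the
second exon; *rejected* otherwise.

Coordinates are 1-based inclusive (GFF3 dialect). Splicing concatenates the
exons in transcription order, reverse-complementing minus-strand loci, so
classification is invariant under strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "GeneRecord",
    "AnnotationConfig",
    "AnnotationError",
    "splice_cds",
    "validate_structure",
    "assign_names",
    "annotate",
    "annotation_frame",
    "read_gene_models",
    "read_fasta",
]

FUNCTIONAL = "functional"
PSEUDOGENE = "pseudogene"
REJECTED = "rejected"

# Defaults for the second-exon motifs. The family signature is the region
# around the catalytic cysteine (GCxAGGT core in plant CHS); the active-site
# motif is the GFGPG loop. Both are configuration, not constants: real
# analyses should supply the motifs appropriate to their alignment.
DEFAULT_SIGNATURE = r"GC[FY]AGGT"
DEFAULT_ACTIVE_SITE = r"GFGPG"


class AnnotationError(ValueError):
    """Raised for malformed gene-model input."""


@dataclass
class GeneRecord:
    """One annotated gene model on a genomic sequence."""

    gene_id: str
    species: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]  # sorted by genomic start
    status: str = ""  # functional / pseudogene / rejected
    assigned_name: str = ""
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.start > self.end:
            raise AnnotationError(f"{self.gene_id}: start > end")
        self.exons = tuple((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if a > b:
                raise AnnotationError(f"{self.gene_id}: exon start > end")
            if a < self.start or b > self.end:
                raise AnnotationError(
                    f"{self.gene_id}: exon ({a},{b}) outside gene span "
                    f"({self.start},{self.end})"
                )
            if prev_end is not None and a <= prev_end:
                raise AnnotationError(
                    f"{self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = b


@dataclass
class AnnotationConfig:
    """Tunable bounds and motifs for the canonical architecture check."""

    exon1_aa_min: int = 37
    exon1_aa_max: int = 64
    exon2_aa_target: int = 340
    exon2_aa_tolerance: int = 10
    signature_pattern: str = DEFAULT_SIGNATURE
    active_site_pattern: str = DEFAULT_ACTIVE_SITE

    def __post_init__(self) -> None:
        if self.exon1_aa_min > self.exon1_aa_max:
            raise AnnotationError("exon1_aa_min > exon1_aa_max")
        if self.exon2_aa_tolerance < 0:
            raise AnnotationError("negative exon2 tolerance")


def _transcription_order(record: GeneRecord) -> tuple[tuple[int, int], ...]:
    return record.exons if record.strand == "+" else tuple(reversed(record.exons))


def splice_cds(genomic: str, record: GeneRecord) -> str:
    """Spliced coding sequence of a record from its chromosome sequence.

    ``genomic`` is the full chromosome/scaffold sequence the coordinates
    refer to. Minus-strand exons are reverse-complemented and concatenated
    in transcription order.
    """
    if not genomic:
        raise AnnotationError(f"{record.gene_id}: empty genomic sequence")
    if record.end > len(genomic):
        raise AnnotationError(
            f"{record.gene_id}: coordinates exceed sequence length {len(genomic)}"
        )
    parts = []
    for a, b in _transcription_order(record):
        piece = genomic[a - 1 : b]
        if record.strand == "-":
            piece = str(Seq(piece).reverse_complement())
        parts.append(piece)
    return "".join(parts).upper()


def _translate(nt: str) -> str:
    """Translate truncating any trailing partial codon; stops become '*'."""
    usable = len(nt) - len(nt) % 3
    if usable == 0:
        return ""
    return str(Seq(nt[:usable]).translate())


def validate_structure(
    record: GeneRecord,
    cds: str,
    config: AnnotationConfig | None = None,
) -> tuple[str, tuple[str, ...]]:
    """Classify one candidate as functional / pseudogene / rejected.

    ``cds`` must be the spliced coding sequence implied by ``record.exons``
    on ``record.strand``. Returns ``(status, reasons)`` where reasons
    enumerate every failed check (empty for functional).
    """
    config = config or AnnotationConfig()
    cds = cds.upper()
    if not cds:
        raise AnnotationError(f"{record.gene_id}: empty coding sequence")
    expected_len = sum(b - a + 1 for a, b in record.exons)
    if len(cds) != expected_len:
        raise AnnotationError(
            f"{record.gene_id}: CDS length {len(cds)} does not match exon "
            f"coordinates (expected {expected_len})"
        )
    reasons: list[str] = []
    exons_tx = _transcription_order(record)
    if len(record.exons) != 2:
        reasons.append("exon_count")
        exon1_nt = len(cds)
        exon2_seq = cds
    else:
        exon1_nt = exons_tx[0][1] - exons_tx[0][0] + 1
        exon2_seq = cds[exon1_nt:]

    # ORF integrity on the full spliced CDS
    has_start = cds.startswith("ATG")
    in_frame = len(cds) % 3 == 0
    protein = _translate(cds)
    internal_stop = "*" in protein[:-1]
    ends_with_stop = in_frame and protein.endswith("*")
    orf_intact = has_start and in_frame and not internal_stop and ends_with_stop
    if not has_start:
        reasons.append("no_start_codon")
    if not in_frame:
        reasons.append("frameshift_length")
    if internal_stop:
        reasons.append("internal_stop")
    if in_frame and not ends_with_stop:
        reasons.append("no_stop_codon")

    # architecture: exon lengths in codons (phase-0 intron expected)
    if len(record.exons) == 2:
        if exon1_nt % 3 != 0:
            reasons.append("intron_phase")
        exon1_aa = exon1_nt // 3
        if not (config.exon1_aa_min <= exon1_aa <= config.exon1_aa_max):
            reasons.append("exon1_length")
        exon2_aa = (len(exon2_seq) - 3) // 3  # excluding the stop codon
        if abs(exon2_aa - config.exon2_aa_target) > config.exon2_aa_tolerance:
            reasons.append("exon2_length")

    # motifs in the in-frame exon-2 translation
    exon2_protein = _translate(exon2_seq)
    sig_in_frame = re.search(config.signature_pattern, exon2_protein) is not None
    act_in_frame = re.search(config.active_site_pattern, exon2_protein) is not None
    if not sig_in_frame:
        reasons.append("signature_missing")
    if not act_in_frame:
        reasons.append("active_site_missing")

    if not reasons:
        return FUNCTIONAL, ()

    if not orf_intact:
        # disrupted ORF: still a pseudogene if the family signature survives
        # in the second-exon region in at least one forward reading frame
        sig_any_frame = any(
            re.search(config.signature_pattern, _translate(exon2_seq[f:]))
            for f in range(3)
        )
        if sig_any_frame:
            return PSEUDOGENE, tuple(reasons)
    return REJECTED, tuple(reasons)


def assign_names(records: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Assign tandem-index names T1..Tn per (species, chromosome) group.

    Numbering follows ascending chromosome start coordinate — the 5' to 3'
    order of the forward strand, regardless of gene strand. Pseudogenes get
    the ``ps`` suffix and still consume an index. Identical start
    coordinates within a group are an error (ambiguous linkage order).
    """
    groups: dict[tuple[str, str], list[GeneRecord]] = {}
    for rec in records:
        groups.setdefault((rec.species, rec.chromosome), []).append(rec)
    out: list[GeneRecord] = []
    for (species, chrom), group in groups.items():
        starts = [r.start for r in group]
        if len(starts) != len(set(starts)):
            dupes = sorted({s for s in starts if starts.count(s) > 1})
            raise AnnotationError(
                f"duplicate start coordinates {dupes} on {species}/{chrom}: "
                "linkage order is ambiguous"
            )
        for i, rec in enumerate(sorted(group, key=lambda r: r.start), start=1):
            suffix = "ps" if rec.status == PSEUDOGENE else ""
            out.append(replace(rec, assigned_name=f"{chrom}-T{i}{suffix}"))
    out.sort(key=lambda r: (r.species, r.chromosome, r.start))
    return out


def annotate(
    records: Sequence[GeneRecord],
    sequences: dict[str, str],
    config: AnnotationConfig | None = None,
) -> list[GeneRecord]:
    """Classify and name a batch of gene models.

    ``sequences`` maps chromosome/scaffold ids to their sequences.
    """
    classified = []
    for rec in records:
        if rec.chromosome not in sequences:
            raise AnnotationError(
                f"{rec.gene_id}: chromosome {rec.chromosome!r} not in FASTA"
            )
        cds = splice_cds(sequences[rec.chromosome], rec)
        status, reasons = validate_structure(rec, cds, config)
        classified.append(replace(rec, status=status, reasons=reasons))
    return assign_names(classified)


def annotation_frame(records: Iterable[GeneRecord]) -> pd.DataFrame:
    """Tabulate records as the pipeline's TSV annotation table."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "species": r.species,
                "chromosome": r.chromosome,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "n_exons": len(r.exons),
                "status": r.status,
                "reasons": ";".join(r.reasons),
                "assigned_name": r.assigned_name,
            }
            for r in records
        ]
    )


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def read_gene_models(gff_path: str, species_of_seqid=None) -> list[GeneRecord]:
    """Read gene models (gene + exon features) from a GFF3 file.

    ``species_of_seqid`` maps a seqid (chromosome) to a species name; when
    omitted the gene feature's ``species`` attribute is used.
    """
    import gffutils

    db = gffutils.create_db(
        gff_path,
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    records = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start, f.end)
            for f in db.children(gene, featuretype="exon")
        )
        if species_of_seqid is not None:
            species = species_of_seqid(gene.seqid)
        else:
            species = gene.attributes.get("species", [""])[0]
        records.append(
            GeneRecord(
                gene_id=gene.id,
                species=species,
                chromosome=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=tuple(exons),
            )
        )
    return records
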