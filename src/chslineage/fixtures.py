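"""Canonical rosid CHS fixture and synthetic CHS-like sequence generator.

This module is the package's synthetic-data stage. It encodes, as concrete
trees and gene models, the published description of chalcone synthase
evolution in 12 rosid species: a dated 12-taxon species tree (root at
~107 my, Fabales crown inside 57-97 my) and an ingroup gene tree of 55
putatively functional genes organised into six ancestral lineages
(conventionally coloured yellow, blue, red, green, brown, pink) whose
per-species copy numbers reproduce the published totals (e.g. barrel medic
17, soybean 15, pink lineage 42 copies, blue lineage 4 cassava genes).

It also fabricates two-exon CHS-like nucleotide sequences (intact ORFs for
functional models, planted disruptions for pseudogenes) so the annotation
stage can be exercised end to end without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .annotation import AnnotationConfig, GeneRecord, FUNCTIONAL, PSEUDOGENE
from .trees import parse_newick

__all__ = [
    "SPECIES",
    "COMPOSITION",
    "CanonicalFixture",
    "build_species_tree",
    "build_gene_tree",
    "build_annotation_records",
    "generate_sequences",
    "write_gff3",
    "write_fasta",
    "canonical_fixture",
    "write_fixture",
    "lineage_color",
]

#: the 12 rosid species, by informal name -> identifier used on tree leaves
SPECIES = {
    "thale cress": "Athaliana",
    "lyrate rockcress": "Alyrata",
    "field mustard": "Brapa",
    "cacao": "Tcacao",
    "cassava": "Mesculenta",
    "castor bean": "Rcommunis",
    "poplar": "Ptrichocarpa",
    "apple": "Mdomestica",
    "wild strawberry": "Fvesca",
    "soybean": "Gmax",
    "barrel medic": "Mtruncatula",
    "Lotus japonicus": "Ljaponicus",
}

#: functional copies per species in each lineage; the pink lineage is split
#: into its two Fabales paralog sub-clades A (medic/lotus-expanded) and B
#: (soybean-expanded), joined by a duplication in the Fabales ancestor.
COMPOSITION: dict[str, dict[str, int]] = {
    "yellow": {"Ptrichocarpa": 1},
    "blue": {"Mesculenta": 4},
    "red": {"Tcacao": 1, "Ptrichocarpa": 1, "Fvesca": 2},
    "green": {
        "Athaliana": 1,
        "Alyrata": 1,
        "Brapa": 4,
        "Gmax": 2,
        "Mtruncatula": 1,
        "Ljaponicus": 1,
    },
    "brown": {
        "Tcacao": 1,
        "Mesculenta": 1,
        "Rcommunis": 1,
        "Ptrichocarpa": 2,
        "Mdomestica": 2,
        "Fvesca": 2,
    },
    "pinkA": {"Mtruncatula": 14, "Ljaponicus": 11, "Gmax": 2},
    "pinkB": {"Mtruncatula": 2, "Ljaponicus": 2, "Gmax": 11},
}

_COLOR_ORDER = ("yellow", "blue", "red", "green", "brown", "pinkA", "pinkB")

# chromosome allocation: species -> [(chromosome, n_functional, n_pseudo)];
# totals match the published per-species counts, including soybean's 15
# genes on 7 chromosomes and single-chromosome repertoires for thale cress,
# lyrate rockcress and castor bean.
_CHROMOSOMES: dict[str, list[tuple[str, int, int]]] = {
    "Athaliana": [("At5", 1, 0)],
    "Alyrata": [("Al7", 1, 0)],
    "Brapa": [("BrA03", 2, 2), ("BrA09", 2, 1)],
    "Tcacao": [("Tc01", 1, 0), ("Tc05", 1, 0)],
    "Mesculenta": [("MeSc06", 3, 0), ("MeSc10", 2, 0)],
    "Rcommunis": [("Rc29931", 1, 0)],
    "Ptrichocarpa": [("Pt06", 2, 0), ("Pt01", 1, 0), ("Pt03", 1, 0)],
    "Mdomestica": [("Md02", 1, 0), ("Md15", 1, 0)],
    "Fvesca": [("Fv02", 3, 0), ("Fv07", 1, 0)],
    "Gmax": [
        ("Gm08", 6, 0),
        ("Gm01", 2, 0),
        ("Gm02", 2, 0),
        ("Gm05", 2, 0),
        ("Gm09", 1, 0),
        ("Gm11", 1, 0),
        ("Gm13", 1, 0),
    ],
    "Mtruncatula": [("Mt01", 8, 1), ("Mt03", 6, 0), ("Mt07", 3, 1)],
    "Ljaponicus": [("Lj01", 7, 1), ("Lj02", 4, 0), ("Lj04", 3, 1)],
}

# Node ages (my). Root and the Fabales crown window are from the published
# calibration (107 my; duplication between 97 and 57 my); the remaining ages
# only need internal consistency and are fixed once here.
_SPECIES_NEWICK = (
    "((((Athaliana:10,Alyrata:10):15,Brapa:25)Brassicales:75,Tcacao:100)"
    "malvids:7,((Ptrichocarpa:95,(Mesculenta:70,Rcommunis:70):25)"
    "Malpighiales:9,((Mdomestica:60,Fvesca:60)Rosales:40,(Gmax:75,"
    "(Mtruncatula:50,Ljaponicus:50):25)Fabales:25):4)fabids:3)rosids;"
)

OUTGROUP_LABEL = "STS_outgroup"


def build_species_tree() -> dendropy.Tree:
    """The dated 12-taxon rosid species tree (ultrametric, root depth 107)."""
    return parse_newick(_SPECIES_NEWICK)


def _cat(labels: list[str]) -> str:
    """Caterpillar newick over labels: (a,(b,(c,d)))."""
    if len(labels) == 1:
        return labels[0]
    return f"({labels[0]},{_cat(labels[1:])})"


def _leaves(color: str, species: str) -> list[str]:
    n = COMPOSITION[color][species]
    return [f"{species}_{color}{i}" for i in range(1, n + 1)]


def _gene_tree_newick() -> str:
    yellow = _leaves("yellow", "Ptrichocarpa")[0]
    blue = _cat(_leaves("blue", "Mesculenta"))
    red = (
        f"(Tcacao_red1,(Ptrichocarpa_red1,"
        f"({','.join(_leaves('red', 'Fvesca'))})))"
    )
    # green: a Brassicales-ancestor duplication — one copy retained only by
    # field mustard, the other carried by thale/lyrate plus a 3-copy field
    # mustard expansion — sister to a species-congruent Fabales subtree.
    bras = (
        "(Brapa_green1,((Athaliana_green1,Alyrata_green1),"
        "(Brapa_green2,(Brapa_green3,Brapa_green4))))"
    )
    fab = "((Gmax_green1,Gmax_green2),(Mtruncatula_green1,Ljaponicus_green1))"
    green = f"({bras},{fab})"
    malp = (
        "((Ptrichocarpa_brown1,Ptrichocarpa_brown2),"
        "(Mesculenta_brown1,Rcommunis_brown1))"
    )
    ros = "((Mdomestica_brown1,Mdomestica_brown2),(Fvesca_brown1,Fvesca_brown2))"
    brown = f"(Tcacao_brown1,({malp},{ros}))"
    pink_a = (
        f"((Gmax_pinkA1,Gmax_pinkA2),"
        f"({_cat(_leaves('pinkA', 'Mtruncatula'))},"
        f"{_cat(_leaves('pinkA', 'Ljaponicus'))}))"
    )
    pink_b = (
        f"({_cat(_leaves('pinkB', 'Gmax'))},"
        f"((Mtruncatula_pinkB1,Mtruncatula_pinkB2),"
        f"(Ljaponicus_pinkB1,Ljaponicus_pinkB2)))"
    )
    pink = f"({pink_a},{pink_b})"
    # backbone ladder: the five joins are duplications mapping to the rosid
    # root, so decomposition yields exactly the six coloured lineages.
    return f"({red},({yellow},({brown},({blue},({green},{pink})))))"


def build_gene_tree(*, with_outgroup: bool = False) -> dendropy.Tree:
    """The canonical 55-leaf ingroup gene tree (optionally plus an STS
    outgroup leaf attached at the root)."""
    ingroup = _gene_tree_newick()
    if with_outgroup:
        return parse_newick(f"({ingroup},{OUTGROUP_LABEL});")
    return parse_newick(ingroup + ";")


def lineage_color(members: frozenset[str] | set[str]) -> str:
    """Colour label of a decomposed lineage, read off its member tags."""
    tags = {m.split("_")[1].rstrip("0123456789") for m in members}
    tags = {"pink" if t.startswith("pink") else t for t in tags}
    if len(tags) != 1:
        raise ValueError(f"members span multiple colour tags: {sorted(tags)}")
    return tags.pop()


_EXON1_AA_CYCLE = (40, 52, 64, 37, 58, 45, 61, 49)
_INTRON_CYCLE = (120, 180, 240, 90, 150)
_PS_MODES = ("internal_stop", "frameshift", "no_start")


def build_annotation_records() -> list[GeneRecord]:
    """Gene models (coordinates + intended status) for every fixture gene.

    Functional gene ids equal the gene-tree leaf labels; pseudogenes
    (2 barrel medic, 2 Lotus japonicus, 3 field mustard) are additional
    records absent from the gene tree. Structure (exon lengths, intron
    lengths, strand, placement) is a deterministic function of the layout
    tables, so the fixture is identical on every build.
    """
    func_ids: dict[str, list[str]] = {sp: [] for sp in _CHROMOSOMES}
    for color in _COLOR_ORDER:
        for species in COMPOSITION[color]:
            func_ids[species].extend(_leaves(color, species))
    records: list[GeneRecord] = []
    gidx = 0
    for species, chroms in _CHROMOSOMES.items():
        queue = list(func_ids[species])
        ps_count = 0
        for chrom, n_func, n_ps in chroms:
            plan: list[tuple[str, str]] = []  # (gene_id, intended status)
            for _ in range(n_func):
                plan.append((queue.pop(0), FUNCTIONAL))
            for _ in range(n_ps):
                ps_count += 1
                plan.append((f"{species}_ps{ps_count}", PSEUDOGENE))
            pos = 1000
            for j, (gene_id, status) in enumerate(plan):
                aa1 = _EXON1_AA_CYCLE[gidx % len(_EXON1_AA_CYCLE)]
                intron = _INTRON_CYCLE[gidx % len(_INTRON_CYCLE)]
                strand = "+" if j % 2 == 0 else "-"
                e1 = 3 * aa1
                if status == PSEUDOGENE and _disruption_mode_for(gene_id) == "frameshift":
                    e1 -= 1  # one-bp deletion in exon 1
                e2 = 3 * 340 + 3  # 340 codons + stop
                if strand == "+":
                    exon1 = (pos, pos + e1 - 1)
                    exon2 = (exon1[1] + intron + 1, exon1[1] + intron + e2)
                    exons = (exon1, exon2)
                else:  # transcription runs right-to-left
                    exon2 = (pos, pos + e2 - 1)
                    exon1 = (exon2[1] + intron + 1, exon2[1] + intron + e1)
                    exons = (exon2, exon1)
                records.append(
                    GeneRecord(
                        gene_id=gene_id,
                        species=species,
                        chromosome=chrom,
                        start=exons[0][0],
                        end=exons[1][1],
                        strand=strand,
                        exons=exons,
                        status=status,
                    )
                )
                pos = exons[1][1] + 500
                gidx += 1
        assert not queue, f"unplaced genes for {species}: {queue}"
    return records


_STOP_FREE_CODONS = None


def _codons_for(aa_seq: str) -> str:
    table = {
        "G": "GGT", "C": "TGT", "F": "TTT", "A": "GCT", "T": "ACT",
        "P": "CCT", "S": "TCT", "L": "CTT", "V": "GTT", "M": "ATG",
    }
    return "".join(table[a] for a in aa_seq)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    global _STOP_FREE_CODONS
    if _STOP_FREE_CODONS is None:
        from Bio.Data.CodonTable import standard_dna_table

        _STOP_FREE_CODONS = sorted(standard_dna_table.forward_table)
    idx = rng.integers(0, len(_STOP_FREE_CODONS), size=n)
    return "".join(_STOP_FREE_CODONS[i] for i in idx)


_SIGNATURE_AA = "GCFAGGT"  # matches the default signature pattern
_ACTIVE_SITE_AA = "GFGPG"  # matches the default active-site pattern
_SIG_OFFSET = 100  # codon offset of the signature within exon 2
_ACT_OFFSET = 320  # codon offset of the active-site motif
_STOP_PLANT_OFFSET = 200  # codon replaced by a stop in disrupted copies


def _gene_sense_sequence(
    record: GeneRecord, rng: np.random.Generator, mode: str | None
) -> tuple[str, str, str]:
    """(exon1, intron, exon2) nucleotide sequences in transcription order."""
    tx = record.exons if record.strand == "+" else tuple(reversed(record.exons))
    e1_len = tx[0][1] - tx[0][0] + 1
    intron_len = (tx[1][0] - tx[0][1] - 1) if record.strand == "+" else (
        tx[0][0] - tx[1][1] - 1
    )
    # minus strand: tx order is (high exon = exon1, low exon = exon2)
    if record.strand == "-":
        intron_len = tx[0][0] - tx[1][1] - 1
    aa1 = (e1_len + 2) // 3  # e1_len is 3*aa1 or 3*aa1-1 (frameshift)
    exon1 = "ATG" + _random_codons(rng, aa1 - 1)
    if mode == "no_start":
        exon1 = "ATC" + exon1[3:]
    if mode == "frameshift":
        exon1 = exon1[:10] + exon1[11:]  # 1-bp deletion
    assert len(exon1) == e1_len
    codons = [
        _random_codons(rng, 1) for _ in range(340)
    ]
    sig = _codons_for(_SIGNATURE_AA)
    act = _codons_for(_ACTIVE_SITE_AA)
    for k in range(len(_SIGNATURE_AA)):
        codons[_SIG_OFFSET + k] = sig[3 * k : 3 * k + 3]
    for k in range(len(_ACTIVE_SITE_AA)):
        codons[_ACT_OFFSET + k] = act[3 * k : 3 * k + 3]
    if mode == "internal_stop":
        codons[_STOP_PLANT_OFFSET] = "TAA"
    exon2 = "".join(codons) + "TAA"
    bases = "ACGT"
    mid = "".join(bases[i] for i in rng.integers(0, 4, size=max(intron_len - 4, 0)))
    intron = ("GT" + mid + "AG")[:intron_len]
    return exon1, intron, exon2


def _disruption_mode_for(gene_id: str) -> str:
    """Disruption planted in a fixture pseudogene, keyed to its ps index so
    record layout and sequence generation always agree."""
    k = int(gene_id.rsplit("_ps", 1)[1])
    return _PS_MODES[(k - 1) % len(_PS_MODES)]


def _disruption_mode(rec: GeneRecord) -> str:
    return _disruption_mode_for(rec.gene_id)


def _revcomp(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).reverse_complement())


def generate_sequences(
    records: list[GeneRecord],
    config: AnnotationConfig | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Fabricate chromosome sequences realising every record.

    Functional records get intact ORFs with the signature and active-site
    motifs planted at fixed codon offsets in exon 2; pseudogene records get
    a planted disruption (internal stop, 1-bp frameshift, or missing start
    codon — cycling deterministically) that leaves the signature region
    detectable. Byte-identical output for a fixed seed.
    """
    del config  # motif choice is fixed to the generator's planted motifs
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[GeneRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    sequences: dict[str, str] = {}
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: r.start)
        length = max(r.end for r in recs) + 500
        bases = "ACGT"
        arr = list(
            bases[i] for i in rng.integers(0, 4, size=length)
        )
        for rec in recs:
            mode = _disruption_mode(rec) if rec.status == PSEUDOGENE else None
            exon1, intron, exon2 = _gene_sense_sequence(rec, rng, mode)
            sense = exon1 + intron + exon2
            forward = sense if rec.strand == "+" else _revcomp(sense)
            assert len(forward) == rec.end - rec.start + 1
            arr[rec.start - 1 : rec.end] = list(forward)
        sequences[chrom] = "".join(arr)
    return sequences


def write_fasta(sequences: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_gff3(records: list[GeneRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in sorted(records, key=lambda r: (r.chromosome, r.start)):
            attrs = f"ID={rec.gene_id};species={rec.species}"
            fh.write(
                f"{rec.chromosome}\tchslineage\tgene\t{rec.start}\t{rec.end}"
                f"\t.\t{rec.strand}\t.\t{attrs}\n"
            )
            for i, (a, b) in enumerate(rec.exons, start=1):
                fh.write(
                    f"{rec.chromosome}\tchslineage\texon\t{a}\t{b}\t.\t"
                    f"{rec.strand}\t.\tID={rec.gene_id}.exon{i};"
                    f"Parent={rec.gene_id}\n"
                )


@dataclass
class CanonicalFixture:
    """The full canonical study fixture: trees, gene models, species map."""

    species_tree: dendropy.Tree
    gene_tree: dendropy.Tree
    records: list[GeneRecord]
    species_map: dict[str, str]

    @property
    def species(self) -> list[str]:
        return [l.taxon.label for l in self.species_tree.leaf_node_iter()]


def canonical_fixture() -> CanonicalFixture:
    gene_tree = build_gene_tree()
    species_map = {
        l.taxon.label: l.taxon.label.split("_")[0]
        for l in gene_tree.leaf_node_iter()
    }
    return CanonicalFixture(
        species_tree=build_species_tree(),
        gene_tree=gene_tree,
        records=build_annotation_records(),
        species_map=species_map,
    )


def write_fixture(outdir: str, seed: int = 0) -> dict[str, str]:
    """Write the fixture inputs (newicks, species map, FASTA, GFF3) to a
    directory; returns the path of each artefact by role."""
    import os

    from .trees import write_newick, write_species_map

    os.makedirs(outdir, exist_ok=True)
    fx = canonical_fixture()
    paths = {
        "species_tree": os.path.join(outdir, "species_tree.nwk"),
        "gene_tree": os.path.join(outdir, "gene_tree.nwk"),
        "gene_tree_with_outgroup": os.path.join(
            outdir, "gene_tree_with_outgroup.nwk"
        ),
        "species_map": os.path.join(outdir, "species_map.tsv"),
        "genome": os.path.join(outdir, "genome.fasta"),
        "gff3": os.path.join(outdir, "gene_models.gff3"),
    }
    with open(paths["species_tree"], "w") as fh:
        fh.write(write_newick(fx.species_tree))
    with open(paths["gene_tree"], "w") as fh:
        fh.write(write_newick(fx.gene_tree))
    with open(paths["gene_tree_with_outgroup"], "w") as fh:
        fh.write(write_newick(build_gene_tree(with_outgroup=True)))
    write_species_map(fx.species_map, paths["species_map"])
    sequences = generate_sequences(fx.records, seed=seed)
    write_fasta(sequences, paths["genome"])
    write_gff3(fx.records, paths["gff3"])
    return paths
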