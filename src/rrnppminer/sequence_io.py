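"""Reading/writing of genome, proteome and table files.

All coordinates are normalized to a single internal convention: 0-based,
half-open intervals on the forward strand, with the strand stored
separately.  GenBank spans (1-based, inclusive, with ``complement(...)``
for the reverse strand) are converted on read and restored on write.
Translation uses the bacterial code (NCBI table 11); ATG/GTG/TTG are
accepted as start codons and codons containing N translate to X.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "Contig",
    "CdsFeature",
    "ProteinRecord",
    "read_genbank",
    "write_genbank",
    "extract_proteome",
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
    "translate_cds",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: NCBI translation table 11 (bacterial); stop codons map to "*".
_CODON_TABLE_11 = {}


def _build_codon_table() -> None:
    bases = "TCAG"
    aas = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                _CODON_TABLE_11[b1 + b2 + b3] = aas[i]
                i += 1


_build_codon_table()

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(nt: str, *, truncate_at_stop: bool = True) -> str:
    """Translate a coding nucleotide sequence (table 11, start forced to M).

    The trailing stop codon, when present, is not included in the protein.
    Codons containing N translate to X.  An internal stop truncates the
    protein with a warning when ``truncate_at_stop`` is set.
    """
    nt = nt.upper()
    aas = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            aas.append("X")
            continue
        aa = _CODON_TABLE_11.get(codon)
        if aa is None:
            aas.append("X")
            continue
        if aa == "*":
            if i == len(nt) - 3:
                break  # terminal stop, not part of the protein
            if truncate_at_stop:
                warnings.warn(
                    f"internal stop codon at nt offset {i}; protein truncated",
                    stacklevel=2,
                )
                break
            break
        aas.append(aa)
    if aas and nt[:3] in START_CODONS:
        aas[0] = "M"
    return "".join(aas)


@dataclass
class CdsFeature:
    """A protein-coding feature on a contig (0-based half-open, forward axis)."""

    feature_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    protein: str
    product: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.feature_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.feature_id}: strand must be '+' or '-'")


@dataclass
class Contig:
    contig_id: str
    sequence: str
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.contig_id}: empty sequence")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(f"{f.feature_id}: feature beyond contig end")

    def feature_nt(self, feat: CdsFeature) -> str:
        """Coding-strand nucleotide sequence of a feature."""
        nt = self.sequence[feat.start : feat.end]
        return reverse_complement(nt) if feat.strand == "-" else nt


@dataclass
class GenomeRecord:
    genome_id: str
    species_label: str
    contigs: list[Contig] = field(default_factory=list)


@dataclass
class ProteinRecord:
    protein_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Parse a GenBank flat file into one GenomeRecord per LOCUS.

    Every record becomes its own single-contig genome unless records share
    a ``/organism`` + DEFINITION-derived genome id via the ``genome_id``
    annotation written by :func:`write_genbank` (multi-contig genomes round
    trip through the ``source`` feature's ``/note`` qualifier).
    """
    path = Path(path)
    genomes: dict[str, GenomeRecord] = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        species = rec.annotations.get("organism", "") or rec.annotations.get(
            "source", ""
        )
        genome_id = rec.id
        features = []
        for feat in rec.features:
            if feat.type == "source":
                note = feat.qualifiers.get("note", [""])[0]
                if note.startswith("genome_id="):
                    genome_id = note.split("=", 1)[1]
                continue
            if feat.type != "CDS":
                continue
            loc = feat.location
            if loc is None:
                raise ValueError(f"malformed CDS in locus {rec.name}: no location")
            start, end = int(loc.start), int(loc.end)
            strand = "-" if loc.strand == -1 else "+"
            protein = feat.qualifiers.get("translation", [None])[0]
            fid = feat.qualifiers.get("locus_tag", feat.qualifiers.get("protein_id", [None]))[0]
            if fid is None:
                fid = f"{rec.name}_{start}_{end}"
            if protein is None:
                nt = str(rec.seq[start:end])
                if strand == "-":
                    nt = reverse_complement(nt)
                protein = translate_cds(nt)
            product = feat.qualifiers.get("product", [""])[0]
            features.append(
                CdsFeature(fid, start, end, strand, protein, product)
            )
        contig = Contig(rec.name or rec.id, str(rec.seq).upper(), features)
        if genome_id in genomes:
            genomes[genome_id].contigs.append(contig)
        else:
            genomes[genome_id] = GenomeRecord(genome_id, species, [contig])
    return list(genomes.values())


def write_genbank(genomes: list[GenomeRecord], path: str | Path) -> None:
    """Write genomes to a GenBank flat file (inverse of :func:`read_genbank`)."""
    records = []
    for g in genomes:
        for contig in g.contigs:
            rec = SeqRecord(
                Seq(contig.sequence),
                id=contig.contig_id,
                name=contig.contig_id[:16],
                description=f"{g.species_label} {g.genome_id}",
            )
            rec.annotations["molecule_type"] = "DNA"
            rec.annotations["organism"] = g.species_label
            src = SeqFeature(
                FeatureLocation(0, len(contig.sequence), strand=1),
                type="source",
                qualifiers={
                    "organism": [g.species_label],
                    "note": [f"genome_id={g.genome_id}"],
                },
            )
            rec.features.append(src)
            for f in contig.features:
                sf = SeqFeature(
                    FeatureLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1),
                    type="CDS",
                    qualifiers={
                        "locus_tag": [f.feature_id],
                        "translation": [f.protein],
                        "product": [f.product],
                        "transl_table": ["11"],
                    },
                )
                rec.features.append(sf)
            records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


def extract_proteome(genome: GenomeRecord) -> list[ProteinRecord]:
    """One ProteinRecord per CDS feature; stop codons are never included."""
    out = []
    for contig in genome.contigs:
        for f in contig.features:
            seq = f.protein
            if not seq:
                seq = translate_cds(contig.feature_nt(f))
            out.append(
                ProteinRecord(
                    protein_id=f.feature_id,
                    genome_id=genome.genome_id,
                    contig_id=contig.contig_id,
                    start=f.start,
                    end=f.end,
                    strand=f.strand,
                    sequence=seq,
                )
            )
    return out


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs; duplicate IDs are an error."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    ids = [i for i, _ in records]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate FASTA ids: {sorted(set(dups))}")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def write_tsv(rows: list[dict], path: str | Path, columns: list[str] | None = None) -> None:
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=columns, delimiter="\t", lineterminator="\n")
        w.writeheader()
        for row in rows:
            w.writerow(row)
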