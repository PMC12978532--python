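"""Gene models: CDS intervals plus spliced coding sequence.

Coordinates follow the two standard dialects — BED intervals are 0-based
half-open, variant positions are 1-based — and every conversion goes through
:func:`bed_to_pos` / :func:`pos_to_bed` so the off-by-one lives in one place.
The FASTA side carries the *spliced* coding sequence of each gene in
transcription order (already reverse-complemented for minus-strand genes),
which is what effect classification consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def bed_to_pos(start0: int) -> int:
    """First base of a 0-based half-open interval as a 1-based position."""
    return start0 + 1


def pos_to_bed(pos1: int) -> int:
    """1-based position as a 0-based offset."""
    return pos1 - 1


class AnnotationError(ValueError):
    """Inconsistent gene annotation (frame, intervals, or sequence)."""


@dataclass
class Gene:
    """One protein-coding gene.

    ``exons`` are CDS intervals in genomic order, 0-based half-open,
    non-overlapping; ``cds`` is the spliced coding sequence in transcription
    order (reverse-complemented when ``strand == '-'``), length divisible
    by 3.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise AnnotationError(f"{self.gene_id}: overlapping CDS intervals")
        span = sum(b - a for a, b in self.exons)
        if span != len(self.cds):
            raise AnnotationError(
                f"{self.gene_id}: CDS length {len(self.cds)} != interval span {span}"
            )
        if len(self.cds) % 3:
            raise AnnotationError(
                f"{self.gene_id}: CDS length {len(self.cds)} not divisible by 3"
            )

    # -- coordinate mapping ------------------------------------------------
    def cds_offset(self, pos1: int) -> int | None:
        """Map a 1-based genomic position to its 0-based offset in the CDS.

        Returns None when the position is not inside any CDS interval.
        """
        p0 = pos_to_bed(pos1)
        off = 0
        for a, b in self.exons:
            if a <= p0 < b:
                fwd = off + (p0 - a)
                if self.strand == "+":
                    return fwd
                return len(self.cds) - 1 - fwd
            off += b - a
        return None

    def splice_region(self, pos1: int) -> bool:
        """True when the position falls in a 2-bp intronic splice dinucleotide.

        Canonical donor/acceptor positions: the first two and last two
        intronic bases between consecutive CDS intervals.
        """
        p0 = pos_to_bed(pos1)
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if b <= p0 < b + 2 or c - 2 <= p0 < c:
                return True
        return False

    def codon_at(self, cds_offset: int) -> tuple[str, int]:
        """Return (codon, position-within-codon) for a CDS offset."""
        idx = cds_offset // 3
        return self.cds[3 * idx: 3 * idx + 3], cds_offset % 3

    def cds_base(self, pos1: int) -> str | None:
        """Reference base at a genomic position, on the coding strand."""
        off = self.cds_offset(pos1)
        return None if off is None else self.cds[off]


@dataclass
class GeneSet:
    genes: list[Gene]
    _by_chrom: dict[str, list[Gene]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_chrom = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def genes_at(self, chrom: str, pos1: int) -> list[Gene]:
        """Genes whose CDS or splice dinucleotides contain the position."""
        out = []
        for g in self._by_chrom.get(chrom, []):
            if g.cds_offset(pos1) is not None or g.splice_region(pos1):
                out.append(g)
        return out


def read_gene_set(bed_path: str | Path, fasta_path: str | Path) -> GeneSet:
    """Assemble a :class:`GeneSet` from BED6 CDS intervals and a CDS FASTA.

    BED lines sharing a name are the CDS exons of one gene (chrom and strand
    must agree).  FASTA records are keyed by gene name and hold the spliced
    coding sequence in transcription order.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    raw: dict[str, dict] = {}
    for line in Path(bed_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise AnnotationError(f"BED6 required, got: {line!r}")
        chrom, start, end, name, _score, strand = f[:6]
        entry = raw.setdefault(name, {"chrom": chrom, "strand": strand, "exons": []})
        if entry["chrom"] != chrom or entry["strand"] != strand:
            raise AnnotationError(f"{name}: inconsistent chrom/strand across exons")
        entry["exons"].append((int(start), int(end)))
    genes = []
    for name, entry in raw.items():
        if name not in seqs:
            raise AnnotationError(f"{name}: no coding sequence in FASTA")
        genes.append(
            Gene(name, entry["chrom"], entry["strand"], entry["exons"], seqs[name])
        )
    return GeneSet(genes)


def write_gene_set(genes: GeneSet, bed_path: str | Path, fasta_path: str | Path) -> None:
    bed_lines = []
    fasta_lines = []
    for g in genes:
        for a, b in g.exons:
            bed_lines.append(f"{g.chrom}\t{a}\t{b}\t{g.gene_id}\t0\t{g.strand}")
        fasta_lines.append(f">{g.gene_id}\n{g.cds}")
    Path(bed_path).write_text("\n".join(bed_lines) + "\n")
    Path(fasta_path).write_text("\n".join(fasta_lines) + "\n")


def translate(cds: str) -> str:
    return str(Seq(cds).translate())
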