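"""Genome model: chromosome sizes plus a TSS-anchored gene annotation.

The :class:`GenomeModel` is the universe for every enrichment test in the
pipeline: it carries chromosome lengths, one transcription start site (TSS)
per gene, the gene's strand, and optional family labels (e.g. ``"TF"`` for
transcription factors, ``"FOX"`` for Forkhead-box genes) used by the
family-enrichment stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


@dataclass(frozen=True)
class Gene:
    """A gene reduced to its TSS anchor.

    Parameters
    ----------
    gene_id : str
        Unique identifier.
    chrom : str
        Chromosome name.
    tss : int
        0-based transcription start site position.
    strand : str
        ``"+"`` or ``"-"``.
    families : frozenset of str
        Family labels the gene carries (possibly empty).
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    families: frozenset = frozenset()


@dataclass
class GenomeModel:
    """Chromosome lengths plus a gene/TSS table.

    Invariants enforced at construction: unique gene ids, every TSS within
    its chromosome, strands in ``{+,-}``, family labels non-empty strings.
    """

    chromosomes: dict[str, int]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in self.chromosomes:
                raise ValueError(f"gene {g.gene_id!r} on unknown chromosome {g.chrom!r}")
            if not (0 <= g.tss < self.chromosomes[g.chrom]):
                raise ValueError(
                    f"gene {g.gene_id!r} TSS {g.tss} outside chromosome "
                    f"{g.chrom!r} (length {self.chromosomes[g.chrom]})"
                )
            if g.strand not in ("+", "-"):
                raise ValueError(f"gene {g.gene_id!r} has invalid strand {g.strand!r}")
            for fam in g.families:
                if not isinstance(fam, str) or not fam:
                    raise ValueError(f"gene {g.gene_id!r} has an empty family label")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def genes_by_chrom(self) -> dict[str, list[Gene]]:
        """Genes grouped by chromosome, sorted by (tss, gene_id)."""
        out: dict[str, list[Gene]] = {c: [] for c in self.chromosomes}
        for g in self.genes:
            out[g.chrom].append(g)
        for c in out:
            out[c].sort(key=lambda g: (g.tss, g.gene_id))
        return out

    def family_map(self) -> dict[str, frozenset]:
        return {g.gene_id: g.families for g in self.genes}

    def family_members(self, label: str) -> set[str]:
        return {g.gene_id for g in self.genes if label in g.families}


def write_gene_table(genome: GenomeModel, path: str | Path) -> None:
    """Write a tab-separated gene table with chromosome sizes in the header.

    Header lines ``#chrom <name> <length>`` carry the chromosome sizes;
    the body columns are ``gene_id  chrom  tss  strand  families`` with
    families comma-joined (``.`` when the gene carries none).
    """
    path = Path(path)
    with path.open("w") as fh:
        for name, length in genome.chromosomes.items():
            fh.write(f"#chrom\t{name}\t{length}\n")
        fh.write("gene_id\tchrom\ttss\tstrand\tfamilies\n")
        for g in genome.genes:
            fams = ",".join(sorted(g.families)) if g.families else "."
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\t{fams}\n")


def read_gene_table(path: str | Path) -> GenomeModel:
    """Read a gene table written by :func:`write_gene_table`."""
    path = Path(path)
    chromosomes: dict[str, int] = {}
    genes: list[Gene] = []
    with path.open() as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#chrom\t"):
                _, name, length = line.split("\t")
                chromosomes[name] = int(length)
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields[0] != "gene_id":
                    raise ValueError(f"{path}:{lineno}: expected gene table header")
                header_seen = True
                continue
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            gene_id, chrom, tss, strand, fams = fields
            families = frozenset() if fams == "." else frozenset(fams.split(","))
            genes.append(Gene(gene_id, chrom, int(tss), strand, families))
    if not chromosomes:
        # fall back to minimal sizes covering the observed TSSs
        for g in genes:
            chromosomes[g.chrom] = max(chromosomes.get(g.chrom, 0), g.tss + 1)
    return GenomeModel(chromosomes=chromosomes, genes=genes)
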