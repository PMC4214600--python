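"""Peak interval handling: BED i/o, peak-to-gene annotation, location
classification, and peak-set intersection.

Annotation follows the window-plus-nearest rule used for distal
regulatory elements: a peak is linked to every TSS within a fixed window
(default 100 kbp) on its chromosome, and, when no TSS falls inside the
window, to the nearest TSS on the same chromosome.  All coordinates are
BED-style 0-based half-open.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import Gene, GenomeModel


@dataclass(frozen=True)
class Peak:
    """A genomic interval, 0-based half-open."""

    peak_id: str
    chrom: str
    start: int
    end: int
    score: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"peak {self.peak_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.summit_offset is not None and not (0 <= self.summit_offset < self.end - self.start):
            raise ValueError(f"peak {self.peak_id!r}: summit offset outside the peak")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def anchor(self, mode: str = "midpoint") -> int:
        """Position used as the distance anchor (summit when available)."""
        if mode == "summit" and self.summit_offset is not None:
            return self.start + self.summit_offset
        return self.midpoint

    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """An ordered collection of peaks."""

    peaks: list[Peak] = field(default_factory=list)
    name: str | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        for c in out:
            out[c].sort(key=lambda p: (p.start, p.end, p.peak_id))
        return out

    def validate_against(self, genome: GenomeModel) -> None:
        for p in self.peaks:
            if p.chrom not in genome.chromosomes:
                raise ValueError(f"peak {p.peak_id!r} on unknown chromosome {p.chrom!r}")
            if p.end > genome.chromosomes[p.chrom]:
                raise ValueError(f"peak {p.peak_id!r} extends past the end of {p.chrom!r}")


@dataclass(frozen=True)
class PeakGeneLink:
    """A rule-tagged peak-to-gene assignment.

    ``distance`` is signed bp from the peak anchor to the TSS, positive
    downstream of the TSS in gene orientation.  ``rule`` records whether
    the link came from the fixed window or from the nearest-TSS fallback.
    """

    peak_id: str
    gene_id: str
    distance: int
    rule: str  # "window" | "nearest"


def read_bed(path: str | Path) -> PeakSet:
    """Read a BED3+ file into a PeakSet.

    0-based half-open intervals are preserved exactly; column 4 supplies
    the peak id (auto-numbered otherwise) and column 5 the score.
    ``track``/``browser``/``#`` header lines are skipped.  Malformed
    lines raise with their line number.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{len(peaks) + 1}"
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            peaks.append(Peak(name, chrom, start, end, score=score))
    return PeakSet(peaks=peaks, name=path.stem)


def write_bed(peakset: PeakSet, path: str | Path) -> None:
    """Write BED6 (name = peak id, score, strand '.')."""
    with Path(path).open("w") as fh:
        for p in peakset:
            score = "0" if p.score is None else f"{p.score:g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{score}\t.\n")


def _signed_distance(anchor: int, gene: Gene) -> int:
    return anchor - gene.tss if gene.strand == "+" else gene.tss - anchor


def annotate_peaks(
    peaks: PeakSet,
    genome: GenomeModel,
    window: int = 100_000,
    anchor: str = "midpoint",
) -> list[PeakGeneLink]:
    """Annotate peaks to genes by the window-plus-nearest-TSS rule.

    Each peak is linked to every gene whose TSS lies within ``window`` bp
    of the peak anchor on the same chromosome (rule ``window``); when no
    TSS is that close, the peak is linked to the nearest TSS on its
    chromosome (rule ``nearest``; all equidistant genes are linked,
    ordered by gene id).  A peak on a chromosome without genes yields no
    link and a warning.
    """
    by_chrom = genome.genes_by_chrom()
    positions = {c: np.array([g.tss for g in gs], dtype=np.int64) for c, gs in by_chrom.items()}
    links: list[PeakGeneLink] = []
    for p in peaks:
        genes = by_chrom.get(p.chrom)
        if genes is None:
            warnings.warn(f"peak {p.peak_id!r}: chromosome {p.chrom!r} not in genome")
            continue
        if not genes:
            warnings.warn(f"peak {p.peak_id!r}: no genes on chromosome {p.chrom!r}")
            continue
        pos = positions[p.chrom]
        mid = p.anchor(anchor)
        lo = int(np.searchsorted(pos, mid - window, side="left"))
        hi = int(np.searchsorted(pos, mid + window, side="right"))
        in_window = [g for g in genes[lo:hi] if abs(mid - g.tss) <= window]
        if in_window:
            for g in sorted(in_window, key=lambda g: g.gene_id):
                links.append(PeakGeneLink(p.peak_id, g.gene_id, _signed_distance(mid, g), "window"))
        else:
            dmin = min(abs(mid - g.tss) for g in genes)
            nearest = sorted(
                (g for g in genes if abs(mid - g.tss) == dmin), key=lambda g: g.gene_id
            )
            for g in nearest:
                links.append(PeakGeneLink(p.peak_id, g.gene_id, _signed_distance(mid, g), "nearest"))
    return links


def classify_peaks(
    peaks: PeakSet,
    genome: GenomeModel,
    promoter_window: int = 2_000,
    body_window: int = 30_000,
    anchor: str = "midpoint",
) -> dict[str, str]:
    """Classify each peak as promoter, intragenic-proxy, or intergenic.

    Without full gene models, the gene body is proxied by ``body_window``
    bp downstream of the TSS in gene orientation.  Precedence is
    promoter > intragenic-proxy > intergenic; the categories are mutually
    exclusive.
    """
    by_chrom = genome.genes_by_chrom()
    out: dict[str, str] = {}
    for p in peaks:
        genes = by_chrom.get(p.chrom, [])
        mid = p.anchor(anchor)
        category = "intergenic"
        if genes:
            if min(abs(mid - g.tss) for g in genes) <= promoter_window:
                category = "promoter"
            else:
                for g in genes:
                    oriented = mid - g.tss if g.strand == "+" else g.tss - mid
                    if 0 <= oriented <= body_window:
                        category = "intragenic-proxy"
                        break
        out[p.peak_id] = category
    return out


def intersect_peaksets(
    a: PeakSet, b: PeakSet, min_overlap: int = 1
) -> list[tuple[Peak, Peak, int]]:
    """All (peak_a, peak_b) pairs overlapping by at least ``min_overlap`` bp.

    Half-open convention: [100, 200) and [200, 300) do not overlap.
    Result is ordered by (chrom, a.start, b.start).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    b_by_chrom = b.by_chrom()
    out: list[tuple[Peak, Peak, int]] = []
    for chrom, a_peaks in sorted(a.by_chrom().items()):
        b_peaks = b_by_chrom.get(chrom)
        if not b_peaks:
            continue
        b_starts = np.array([q.start for q in b_peaks], dtype=np.int64)
        b_ends = np.array([q.end for q in b_peaks], dtype=np.int64)
        for pa in a_peaks:
            ov = np.minimum(pa.end, b_ends) - np.maximum(pa.start, b_starts)
            for j in np.nonzero(ov >= min_overlap)[0]:
                out.append((pa, b_peaks[int(j)], int(ov[j])))
    return out


def links_to_tsv(links: Sequence[PeakGeneLink], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("peak_id\tgene_id\tdistance\trule\n")
        for ln in links:
            fh.write(f"{ln.peak_id}\t{ln.gene_id}\t{ln.distance}\t{ln.rule}\n")


def read_links_tsv(path: str | Path) -> list[PeakGeneLink]:
    links: list[PeakGeneLink] = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["peak_id", "gene_id", "distance", "rule"]:
            raise ValueError(f"{path}: unexpected link-table header")
        for line in fh:
            if not line.strip():
                continue
            peak_id, gene_id, distance, rule = line.rstrip("\n").split("\t")[:4]
            links.append(PeakGeneLink(peak_id, gene_id, int(distance), rule))
    return links
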