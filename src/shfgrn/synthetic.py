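"""Synthetic genomes, expression datasets, peak sets, and enhancer
sequences with known planted structure.

Every simulator takes an explicit seed and is deterministic for a fixed
seed.  The defaults emulate the scale of a pooled mouse-embryo
microarray/ChIP study: a TSS-annotated genome, 4 mutant vs 3 wild-type
pooled arrays with log-normal intensities and per-array scale jitter,
peaks placed near or far from TSSs, and sequences carrying an exact
GLI-consensus + T-box site pair at controlled spacing.  The planted
structure is returned as a :class:`SyntheticTruth` so downstream stages
can be scored against ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionDataset
from .genome import Gene, GenomeModel
from .motifs import IUPAC, Motif, revcomp
from .peaks import Peak, PeakSet


class SizingError(ValueError):
    """Requested geometry does not fit (chromosome or sequence too short)."""


@dataclass
class SyntheticTruth:
    """Ground truth for planted structure.

    ``de_genes`` maps gene id to its planted log2 fold change;
    ``target_peaks`` maps peak id to the gene whose TSS it was placed
    near; ``motif_pairs`` maps sequence id to the planted pair record
    (site coordinates in plus-strand half-open coordinates, strand, and
    edge-to-edge gap).
    """

    de_genes: dict = field(default_factory=dict)
    target_peaks: dict = field(default_factory=dict)
    motif_pairs: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": self.de_genes,
            "target_peaks": self.target_peaks,
            "motif_pairs": self.motif_pairs,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            de_genes=payload.get("de_genes", {}),
            target_peaks=payload.get("target_peaks", {}),
            motif_pairs=payload.get("motif_pairs", {}),
        )


def simulate_genome(
    n_chrom: int,
    n_genes: int,
    chrom_len: int,
    family_fractions: Mapping[str, float] | None = None,
    seed: int = 0,
    min_spacing: int = 5_000,
) -> GenomeModel:
    """A genome with uniformly placed TSSs at a minimum spacing.

    Genes are distributed as evenly as possible over ``n_chrom``
    chromosomes of equal length; TSS positions are uniform subject to a
    minimum inter-TSS spacing (default 5 kbp); strands and family labels
    are seeded Bernoulli draws (each label independent, so labels can
    co-occur on a gene).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    family_fractions = dict(family_fractions or {})
    for label, frac in family_fractions.items():
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"family fraction for {label!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    counts = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0) for i in range(n_chrom)]
    chromosomes = {f"chr{i + 1}": chrom_len for i in range(n_chrom)}
    genes: list[Gene] = []
    width = len(str(n_genes))
    gi = 0
    for ci, (chrom, k) in enumerate(zip(chromosomes, counts)):
        if k == 0:
            continue
        span = chrom_len - (k - 1) * min_spacing
        if span < 1:
            raise SizingError(
                f"chromosome length {chrom_len} too short for {k} genes "
                f"at spacing {min_spacing}"
            )
        draws = np.sort(rng.integers(0, span, size=k))
        positions = draws + np.arange(k) * min_spacing
        strands = rng.choice(np.array(["+", "-"]), size=k)
        for tss, strand in zip(positions, strands):
            gi += 1
            genes.append(Gene(f"g{gi:0{width}d}", chrom, int(tss), str(strand)))
    # family labels assigned genome-wide so fractions hold overall
    labels_per_gene: list[set[str]] = [set() for _ in range(n_genes)]
    for label in sorted(family_fractions):
        mask = rng.random(n_genes) < family_fractions[label]
        for i in np.nonzero(mask)[0]:
            labels_per_gene[int(i)].add(label)
    genes = [
        Gene(g.gene_id, g.chrom, g.tss, g.strand, frozenset(labels_per_gene[i]))
        for i, g in enumerate(genes)
    ]
    return GenomeModel(chromosomes=chromosomes, genes=genes)


def simulate_expression(
    genome: GenomeModel,
    n_case: int = 4,
    n_ctrl: int = 3,
    de_spec: Mapping | None = None,
    noise_sd: float = 0.25,
    seed: int = 0,
    probes_per_gene: float = 1.3,
    frac_unannotated: float = 0.05,
    qc_fail_rate: float = 0.002,
    scale_jitter_sd: float = 0.1,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Pooled case/control expression with planted differential genes.

    Intensities are log-normal: log2 intensity = probe baseline +
    planted log2FC (case columns of DE genes) + per-array scale jitter +
    Gaussian noise.  ``de_spec`` is ``{"n_down": int, "n_up": int,
    "lfc_range": (lo, hi)}``; planted |log2FC| values are uniform in the
    range (down genes negative).  Probes map many-to-one onto genes
    (default 1.3 probes/gene); a fraction of extra probes is unannotated
    and QC-fail flags are injected at ``qc_fail_rate``.
    """
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("need at least 2 samples per group")
    de_spec = dict(de_spec or {})
    n_down = int(de_spec.get("n_down", 0))
    n_up = int(de_spec.get("n_up", 0))
    lfc_lo, lfc_hi = de_spec.get("lfc_range", (2.0, 3.0))
    if n_down + n_up > genome.n_genes:
        raise ValueError("de_spec plants more DE genes than the genome has")
    rng = np.random.default_rng(seed)
    gene_ids = genome.gene_ids()

    de_idx = rng.choice(genome.n_genes, size=n_down + n_up, replace=False)
    lfc_by_gene: dict[str, float] = {}
    for j, i in enumerate(de_idx):
        mag = float(rng.uniform(lfc_lo, lfc_hi))
        lfc_by_gene[gene_ids[int(i)]] = -mag if j < n_down else mag

    n_probes = int(round(probes_per_gene * genome.n_genes))
    probe_gene: list[str | None] = list(gene_ids)
    extra = n_probes - genome.n_genes
    if extra > 0:
        probe_gene += [gene_ids[int(i)] for i in rng.integers(0, genome.n_genes, size=extra)]
    n_unannot = int(round(frac_unannotated * len(probe_gene)))
    probe_gene += [None] * n_unannot
    probe_ids = [f"p{i + 1:06d}" for i in range(len(probe_gene))]
    probe_map = dict(zip(probe_ids, probe_gene))

    samples = [f"case_{i + 1}" for i in range(n_case)] + [f"ctrl_{i + 1}" for i in range(n_ctrl)]
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}
    n_samp = len(samples)

    baseline = rng.normal(baseline_mean, baseline_sd, size=len(probe_ids))
    array_effect = rng.normal(0.0, scale_jitter_sd, size=n_samp)
    lfc_per_probe = np.array([lfc_by_gene.get(g, 0.0) if g else 0.0 for g in probe_gene])
    log2 = (
        baseline[:, None]
        + array_effect[None, :]
        + rng.normal(0.0, noise_sd, size=(len(probe_ids), n_samp))
    )
    log2[:, :n_case] += lfc_per_probe[:, None]
    values = pd.DataFrame(np.exp2(log2), index=probe_ids, columns=samples)
    qc = pd.DataFrame(
        rng.random((len(probe_ids), n_samp)) >= qc_fail_rate, index=probe_ids, columns=samples
    )
    ds = ExpressionDataset(values=values, probe_map=probe_map, groups=groups, qc_flags=qc)
    return ds, SyntheticTruth(de_genes=lfc_by_gene)


def simulate_peaks(
    genome: GenomeModel,
    n_peaks: int,
    frac_near_tss: float = 0.5,
    near_window: int = 1_000,
    peak_width: int = 500,
    target_genes: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[PeakSet, SyntheticTruth]:
    """Peaks placed near TSSs of (target) genes or uniformly at random.

    ``frac_near_tss`` of the peaks get their midpoint within
    ``near_window`` bp of a target-gene TSS (cycling deterministically
    through the target list so every target receives a peak when there
    are enough near peaks); the remainder are uniform over the genome.
    No peak crosses a chromosome boundary.
    """
    if any(peak_width >= ln for ln in genome.chromosomes.values()):
        raise SizingError("peak width not smaller than a chromosome")
    if not (0.0 <= frac_near_tss <= 1.0):
        raise ValueError("frac_near_tss outside [0, 1]")
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in genome.genes}
    if target_genes is not None:
        missing = [g for g in target_genes if g not in by_id]
        if missing:
            raise ValueError(f"target genes not in genome: {missing[:5]}")
        pool = list(target_genes)
    else:
        pool = genome.gene_ids()
    if not pool and n_peaks and frac_near_tss > 0:
        raise ValueError("no genes available for near-TSS placement")

    n_near = int(round(frac_near_tss * n_peaks))
    half = peak_width // 2
    chrom_names = list(genome.chromosomes)
    chrom_lens = np.array([genome.chromosomes[c] for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    peaks: list[Peak] = []
    truth = SyntheticTruth()
    width = len(str(max(n_peaks, 1)))
    for i in range(n_peaks):
        pid = f"peak_{i + 1:0{width}d}"
        if i < n_near:
            gene = by_id[pool[i % len(pool)]]
            offset = int(rng.integers(-near_window, near_window + 1)) if near_window else 0
            mid = gene.tss + offset
            chrom = gene.chrom
            truth.target_peaks[pid] = gene.gene_id
        else:
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
            mid = int(rng.integers(half, genome.chromosomes[chrom] - (peak_width - half) + 1))
        clen = genome.chromosomes[chrom]
        mid = min(max(mid, half), clen - (peak_width - half))
        start = mid - half
        peaks.append(Peak(pid, chrom, start, start + peak_width))
    return PeakSet(peaks=peaks, name="synthetic"), truth


def _realize_consensus(motif: Motif, rng: np.random.Generator) -> str:
    """A concrete ACGT realization of a (possibly degenerate) consensus."""
    return "".join(
        c if c in "ACGT" else IUPAC[c][int(rng.integers(len(IUPAC[c])))]
        for c in motif.consensus
    )


def plant_motif_pairs(
    n_seqs: int,
    seq_len: int,
    motif_a: Motif,
    motif_b: Motif,
    gap: int = 30,
    frac_planted: float = 1.0,
    seed: int = 0,
    seq_ids: Sequence[str] | None = None,
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Random sequences, a fraction carrying an exact a-gap-b site pair.

    Background is i.i.d. uniform ACGT.  In planted sequences the
    consensus of ``motif_a``, ``gap`` background bases, then the
    consensus of ``motif_b`` are written at a random offset; the whole
    cassette is reverse-complemented when the (random) planted strand is
    minus.  Truth records plus-strand half-open coordinates per site and
    the edge-to-edge gap.
    """
    la, lb = len(motif_a), len(motif_b)
    if seq_len < la + gap + lb:
        raise SizingError(
            f"seq_len {seq_len} cannot hold {la}+{gap}+{lb} bp of planted pair"
        )
    if not (0.0 <= frac_planted <= 1.0):
        raise ValueError("frac_planted outside [0, 1]")
    if seq_ids is not None and len(seq_ids) != n_seqs:
        raise ValueError("seq_ids length must equal n_seqs")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    n_planted = int(round(frac_planted * n_seqs))
    records: list[tuple[str, str]] = []
    truth = SyntheticTruth()
    for i in range(n_seqs):
        sid = seq_ids[i] if seq_ids is not None else f"seq_{i + 1:04d}"
        seq = list(rng.choice(bases, size=seq_len))
        if i < n_planted:
            site_a = _realize_consensus(motif_a, rng)
            site_b = _realize_consensus(motif_b, rng)
            cassette = site_a + "".join(rng.choice(bases, size=gap)) + site_b
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(0, seq_len - len(cassette) + 1))
            placed = cassette if strand == "+" else revcomp(cassette)
            seq[start : start + len(cassette)] = list(placed)
            if strand == "+":
                a_start, b_start = start, start + la + gap
            else:
                # cassette reversed: b comes first on the plus strand
                b_start, a_start = start, start + lb + gap
            truth.motif_pairs[sid] = {
                "strand": strand,
                "a": {"motif_id": motif_a.motif_id, "start": a_start, "end": a_start + la},
                "b": {"motif_id": motif_b.motif_id, "start": b_start, "end": b_start + lb},
                "gap": gap,
            }
        records.append((sid, "".join(seq)))
    return records, truth


def sample_enriched_targets(
    genome: GenomeModel,
    label: str,
    n_targets: int,
    weight: float = 3.0,
    seed: int = 0,
) -> set[str]:
    """Sample a target gene set in which label-carrying genes are
    over-represented with the given sampling odds multiplier."""
    if n_targets > genome.n_genes:
        raise ValueError("more targets requested than genes available")
    rng = np.random.default_rng(seed)
    gene_ids = np.array(genome.gene_ids())
    w = np.array([weight if label in g.families else 1.0 for g in genome.genes], dtype=float)
    w /= w.sum()
    chosen = rng.choice(len(gene_ids), size=n_targets, replace=False, p=w)
    return set(gene_ids[chosen])
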