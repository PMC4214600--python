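"""Signature/peak-set integration and Fisher-exact enrichment.

The central objects are 2x2 contingency tables comparing gene sets over
an explicit universe: signature genes vs peak-bound genes, target genes
vs a gene family, affected vs unaffected embryos by genotype.  The odds
ratio reported is the unconditional cross-product ``a*d / (b*c)`` (not
the conditional maximum-likelihood estimate), with infinity/zero markers
for empty cells; the p-value is the exact hypergeometric Fisher p.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .peaks import PeakGeneLink


@dataclass(frozen=True)
class EnrichmentResult:
    """A 2x2 contingency table with its odds ratio and Fisher-exact p.

    Cell layout: ``a`` in both sets, ``b`` in set A only, ``c`` in set B
    only, ``d`` in neither; ``N = a+b+c+d``.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    sidedness: str

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "N": self.n_total,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "sidedness": self.sidedness,
        }


def cross_product_odds_ratio(a: int, b: int, c: int, d: int, haldane: bool = False) -> float:
    """Unconditional cross-product odds ratio a*d/(b*c).

    Zero cells: returns ``inf`` when b*c == 0 and a*d > 0, ``0.0`` when
    a*d == 0 and b*c > 0, and ``nan`` when both products vanish.  With
    ``haldane`` a 0.5 continuity correction is added to every cell.
    """
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5  # type: ignore[assignment]
    num, den = a * d, b * c
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def fet_2x2(
    a: int, b: int, c: int, d: int, sidedness: str = "two", haldane: bool = False
) -> EnrichmentResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    ``sidedness`` is ``"two"`` (two-sided: sum of table probabilities no
    larger than the observed table's) or ``"one"`` (over-representation
    of cell ``a``).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("contingency counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    if sidedness not in ("one", "two"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    alternative = "greater" if sidedness == "one" else "two-sided"
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    orr = cross_product_odds_ratio(a, b, c, d, haldane=haldane)
    return EnrichmentResult(a, b, c, d, orr, float(p), sidedness)


def enrichment_fet_counts(
    n_overlap: int, n_a: int, n_b: int, universe_n: int, sidedness: str = "one"
) -> EnrichmentResult:
    """Enrichment of two gene sets given their sizes and overlap."""
    if not (0 <= n_overlap <= min(n_a, n_b) <= universe_n):
        raise ValueError("inconsistent set sizes")
    b = n_a - n_overlap
    c = n_b - n_overlap
    d = universe_n - n_a - n_b + n_overlap
    if d < 0:
        raise ValueError("set sizes exceed the universe")
    return fet_2x2(n_overlap, b, c, d, sidedness=sidedness)


def enrichment_fet(
    set_a: Iterable[str], set_b: Iterable[str], universe_n: int, sidedness: str = "one"
) -> EnrichmentResult:
    """Enrichment between two explicit gene sets over a universe of size N."""
    sa, sb = set(set_a), set(set_b)
    return enrichment_fet_counts(len(sa & sb), len(sa), len(sb), universe_n, sidedness=sidedness)


@dataclass
class TargetSet:
    """Genes in the signature that carry at least one contributing peak."""

    genes: set = field(default_factory=set)
    peaks: set = field(default_factory=set)
    gene_peaks: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def intersect_signature(links: Sequence[PeakGeneLink], sig) -> TargetSet:
    """Intersect peak-to-gene links with an expression signature.

    ``sig`` may be a :class:`shfgrn.expression.GeneSignature` or any
    iterable of gene ids.  Peak and gene counts are tracked separately: a
    peak may contribute to several genes and a gene may carry several
    peaks.
    """
    sig_genes = set(sig.genes) if hasattr(sig, "genes") else set(sig)
    link_genes = {ln.gene_id for ln in links}
    if links and sig_genes and not (link_genes & sig_genes):
        warnings.warn(
            "no gene-id overlap between peak links and signature: "
            "possible gene-id namespace mismatch"
        )
    ts = TargetSet()
    for ln in links:
        if ln.gene_id in sig_genes:
            ts.genes.add(ln.gene_id)
            ts.peaks.add(ln.peak_id)
            ts.gene_peaks.setdefault(ln.gene_id, set()).add(ln.peak_id)
    return ts


def family_enrichment(
    targets: TargetSet | Iterable[str],
    family_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    label: str,
    sidedness: str = "one",
) -> EnrichmentResult:
    """Enrichment of a gene-family label among target genes.

    ``family_map`` maps gene id to its family labels; ``label`` must
    occur somewhere in the map.  The contingency table compares target
    genes with label-carrying genes over the universe.
    """
    if not any(label in fams for fams in family_map.values()):
        raise ValueError(f"family label {label!r} absent from the family map")
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    target_genes = targets.genes if isinstance(targets, TargetSet) else set(targets)
    members = {g for g in uni if label in family_map.get(g, ())}
    return enrichment_fet(set(target_genes) & uni, members, len(uni), sidedness=sidedness)


def synergy_index(fold_a: float, fold_b: float, fold_ab: float) -> dict:
    """Super-additivity of reporter fold inductions.

    Folds are relative to a baseline of 1; the excess over the additive
    expectation is ``fold_ab - (fold_a + fold_b - 1)``.  This is a
    descriptive index of synergy, not a hypothesis test.
    """
    if fold_a < 0 or fold_b < 0 or fold_ab < 0:
        raise ValueError("fold inductions must be non-negative")
    excess = fold_ab - (fold_a + fold_b - 1)
    return {"excess_over_additive": excess, "is_super_additive": excess > 0}


def targets_to_tsv(targets: TargetSet, path: str | Path, de_table=None) -> None:
    """Write the target set as TSV (gene_id, peak_ids[, fc, q])."""
    with Path(path).open("w") as fh:
        cols = "gene_id\tpeak_ids"
        if de_table is not None:
            cols += "\tfc\tq"
        fh.write(cols + "\n")
        for gene in sorted(targets.genes):
            peak_ids = ",".join(sorted(targets.gene_peaks.get(gene, ())))
            row = f"{gene}\t{peak_ids}"
            if de_table is not None and gene in de_table.index:
                row += f"\t{de_table.loc[gene, 'fc']:.6g}\t{de_table.loc[gene, 'q']:.6g}"
            elif de_table is not None:
                row += "\t.\t."
            fh.write(row + "\n")


def enrichments_to_tsv(results: Mapping[str, EnrichmentResult], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("comparison\ta\tb\tc\td\tN\todds_ratio\tp_value\tsidedness\n")
        for name, r in results.items():
            fh.write(
                f"{name}\t{r.a}\t{r.b}\t{r.c}\t{r.d}\t{r.n_total}\t"
                f"{r.odds_ratio:.6g}\t{r.p_value:.6g}\t{r.sidedness}\n"
            )
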