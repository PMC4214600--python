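"""Consensus-motif scanning and heterotypic co-occurrence pairing.

GLI zinc-finger effectors and T-box factors recognise short degenerate
sites; enhancers that integrate both pathways carry the two site classes
within a few tens of base pairs of each other.  This module scans
sequences for IUPAC consensus matches with a mismatch budget, pairs
heterotypic sites by edge-to-edge gap, and tests known-motif enrichment
of a foreground sequence set against a background (observed or
dinucleotide-shuffled).

Built-in motifs
---------------
``GLI``  ``CGTGGGTGGTCC`` — the ChIP-derived GLI consensus (12-mer,
default mismatch budget 2: natural GLI sites often deviate from the
consensus at one or two positions).

``TBX``  ``AGGTGTGG`` — the canonical T-box half-site (8-mer, exact by
default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    """An IUPAC consensus motif."""

    motif_id: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("empty consensus")
        cons = self.consensus.upper()
        bad = set(cons) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in consensus: {sorted(bad)}")
        object.__setattr__(self, "consensus", cons)

    def __len__(self) -> int:
        return len(self.consensus)

    def match_probability(self) -> float:
        """Per-window match probability on i.i.d. uniform ACGT (0 mismatches)."""
        p = 1.0
        for c in self.consensus:
            p *= len(IUPAC[c]) / 4.0
        return p


#: Built-in motifs: the ChIP-derived GLI consensus and the canonical
#: T-box binding site.
BUILTIN_MOTIFS: dict[str, Motif] = {
    "GLI": Motif("GLI", "CGTGGGTGGTCC"),
    "TBX": Motif("TBX", "AGGTGTGG"),
}

#: Default mismatch budget per built-in motif (GLI sites commonly deviate
#: from the 12-mer consensus at up to two positions; the 8-mer T-box site
#: is matched exactly).
DEFAULT_MAX_MISMATCH: dict[str, int] = {"GLI": 2, "TBX": 0}

# Published Foxf1a enhancer sites (mouse chr8, mm9 assembly, 1-based
# inclusive starts): a canonical T-box site and a GLI site lying on the
# minus strand relative to the GLI consensus.
FOXF1A_TBX_SITE_SEQ = "AGGTGTGG"
FOXF1A_TBX_SITE_START_1BASED = 123_517_714
FOXF1A_GLI_SITE_SEQ = "GGACCACCCAGC"
FOXF1A_GLI_SITE_START_1BASED = 123_517_754
FOXF1A_REGION_CHROM = "chr8"


@dataclass(frozen=True)
class MotifSite:
    """A located motif occurrence, always in plus-strand coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    motif_id: str


@dataclass(frozen=True)
class CoSitePair:
    """A heterotypic pair of sites on the same sequence.

    ``gap`` is the edge-to-edge distance in bp under half-open
    coordinates; overlapping or abutting sites have gap 0.
    """

    site_a: MotifSite
    site_b: MotifSite
    gap: int


def _match_table(consensus: str) -> np.ndarray:
    """Boolean table[j, byte] = does sequence byte match consensus[j].

    An ``N`` in the *sequence* never matches, whatever the consensus.
    """
    table = np.zeros((len(consensus), 256), dtype=bool)
    for j, c in enumerate(consensus):
        for b in IUPAC[c]:
            table[j, ord(b)] = True
    table[:, ord("N")] = False
    return table


def _scan_one_strand(arr: np.ndarray, consensus: str, max_mismatch: int) -> list[tuple[int, int]]:
    m = len(consensus)
    n_win = len(arr) - m + 1
    if n_win <= 0:
        return []
    table = _match_table(consensus)
    mm = np.zeros(n_win, dtype=np.int32)
    for j in range(m):
        mm += ~table[j, arr[j : j + n_win]]
    hits = np.nonzero(mm <= max_mismatch)[0]
    return [(int(i), int(mm[i])) for i in hits]


def scan_consensus(
    seq: str,
    motif: Motif,
    max_mismatch: int = 0,
    both_strands: bool = True,
    seq_id: str = "seq",
) -> list[MotifSite]:
    """Find all occurrences of ``motif`` in ``seq`` within a mismatch budget.

    Every window (on both strands when ``both_strands``) whose mismatch
    count against the IUPAC consensus is at most ``max_mismatch`` is
    reported; minus-strand hits are reported in plus-strand coordinates.
    Sequence ``N`` bases never match.
    """
    if max_mismatch >= len(motif):
        raise ValueError("max_mismatch must be smaller than the motif length")
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    m = len(motif)
    sites = [
        MotifSite(seq_id, i, i + m, "+", mm, motif.motif_id)
        for i, mm in _scan_one_strand(arr, motif.consensus, max_mismatch)
    ]
    if both_strands:
        rc = revcomp(motif.consensus)
        sites += [
            MotifSite(seq_id, i, i + m, "-", mm, motif.motif_id)
            for i, mm in _scan_one_strand(arr, rc, max_mismatch)
        ]
    sites.sort(key=lambda t: (t.start, t.strand))
    return sites


def site_gap(a: MotifSite, b: MotifSite) -> int:
    """Edge-to-edge distance between two half-open intervals (0 if overlapping)."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def find_adjacent_pairs(
    sites_a: Sequence[MotifSite],
    sites_b: Sequence[MotifSite],
    max_gap: int = 50,
) -> list[CoSitePair]:
    """All heterotypic (a, b) pairs on the same sequence with gap <= max_gap.

    The default window of 50 bp comfortably covers the few-tens-of-bp
    spacing characteristic of co-regulated enhancer site pairs. The
    result is sorted by (seq_id, gap) and is invariant to the ordering of
    the input site lists.
    """
    by_seq: dict[str, list[MotifSite]] = {}
    for sb in sites_b:
        by_seq.setdefault(sb.seq_id, []).append(sb)
    pairs: list[CoSitePair] = []
    for sa in sites_a:
        for sb in by_seq.get(sa.seq_id, ()):
            g = site_gap(sa, sb)
            if g <= max_gap:
                pairs.append(CoSitePair(sa, sb, g))
    pairs.sort(
        key=lambda p: (p.site_a.seq_id, p.gap, p.site_a.start, p.site_b.start, p.site_a.strand, p.site_b.strand)
    )
    return pairs


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul–Erickson scheme: pick a random last-edge arborescence toward
    the terminal base, shuffle the remaining edges, and walk the Eulerian
    path from the original first base.
    """
    s = seq.upper()
    if len(s) < 3:
        return s
    chars = sorted(set(s))
    edges: dict[str, list[str]] = {c: [] for c in chars}
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]
    while True:
        last_edge: dict[str, str] = {}
        for c in chars:
            if c == last or not edges[c]:
                continue
            last_edge[c] = edges[c][int(rng.integers(len(edges[c])))]
        ok = True
        for c in last_edge:
            seen: set[str] = set()
            v: str | None = c
            while v is not None and v != last and v not in seen:
                seen.add(v)
                v = last_edge.get(v)
            if v != last:
                ok = False
                break
        if ok:
            break
    out_edges: dict[str, list[str]] = {}
    for c in chars:
        lst = list(edges[c])
        if c in last_edge:
            lst.remove(last_edge[c])
        idx = rng.permutation(len(lst))
        lst = [lst[i] for i in idx]
        if c in last_edge:
            lst.append(last_edge[c])
        out_edges[c] = lst
    result = [s[0]]
    v = s[0]
    cursor = {c: 0 for c in chars}
    while cursor[v] < len(out_edges[v]):
        nxt = out_edges[v][cursor[v]]
        cursor[v] += 1
        result.append(nxt)
        v = nxt
    return "".join(result)


def motif_enrichment(
    fg_seqs: Sequence[tuple[str, str]] | Sequence[str],
    motif: Motif,
    max_mismatch: int = 0,
    bg_seqs: Sequence[tuple[str, str]] | Sequence[str] | None = None,
    seed: int | None = None,
    sidedness: str = "one",
):
    """Known-motif enrichment of foreground vs background sequences.

    Presence/absence of at least one site is tabulated per sequence and
    tested with Fisher's exact test.  When ``bg_seqs`` is omitted the
    background is a per-sequence dinucleotide shuffle of the foreground
    (seeded via ``seed``).

    Returns an :class:`shfgrn.integrate.EnrichmentResult` with counts
    (fg-with, fg-without, bg-with, bg-without).
    """
    from .integrate import fet_2x2

    fg = _as_records(fg_seqs, prefix="fg")
    if not fg:
        raise ValueError("empty foreground sequence set")
    if any(len(s) < len(motif) for _, s in fg):
        raise ValueError("motif longer than a foreground sequence")
    if bg_seqs is None:
        rng = np.random.default_rng(seed)
        bg = [(f"shuf_{sid}", dinucleotide_shuffle(s, rng)) for sid, s in fg]
    else:
        bg = _as_records(bg_seqs, prefix="bg")
        if not bg:
            raise ValueError("empty background sequence set")

    def n_with(records: list[tuple[str, str]]) -> int:
        return sum(
            1
            for sid, s in records
            if scan_consensus(s, motif, max_mismatch=max_mismatch, seq_id=sid)
        )

    fg_with = n_with(fg)
    bg_with = n_with(bg)
    return fet_2x2(fg_with, len(fg) - fg_with, bg_with, len(bg) - bg_with, sidedness=sidedness)


def _as_records(seqs, prefix: str = "seq") -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    for i, item in enumerate(seqs):
        if isinstance(item, str):
            records.append((f"{prefix}_{i}", item))
        else:
            sid, s = item
            records.append((str(sid), str(s)))
    return records


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) records.

    Wrapped sequence lines are concatenated; case is preserved as read
    (scanning upper-cases internally). Duplicate ids and empty records
    are errors.
    """
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with path.open() as fh:
        for title, seq in SimpleFastaParser(fh):
            sid = title.split()[0] if title.split() else ""
            if not sid:
                raise ValueError(f"{path}: record with empty id")
            if sid in seen:
                raise ValueError(f"{path}: duplicate sequence id {sid!r}")
            if not seq:
                raise ValueError(f"{path}: empty sequence for {sid!r}")
            seen.add(sid)
            records.append((sid, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def sites_to_tsv(sites: Sequence[MotifSite], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("seq_id\tstart\tend\tstrand\tmismatches\tmotif_id\n")
        for s in sites:
            fh.write(f"{s.seq_id}\t{s.start}\t{s.end}\t{s.strand}\t{s.mismatches}\t{s.motif_id}\n")


def pairs_to_tsv(pairs: Sequence[CoSitePair], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "seq_id\tmotif_a\tstart_a\tend_a\tstrand_a\tmotif_b\tstart_b\tend_b\tstrand_b\tgap\n"
        )
        for p in pairs:
            a, b = p.site_a, p.site_b
            fh.write(
                f"{a.seq_id}\t{a.motif_id}\t{a.start}\t{a.end}\t{a.strand}\t"
                f"{b.motif_id}\t{b.start}\t{b.end}\t{b.strand}\t{p.gap}\n"
            )


def foxf1a_example_region(flank: int = 100, seed: int = 20140604) -> tuple[str, int]:
    """A synthetic stand-in for the Foxf1a enhancer neighbourhood.

    Embeds the two published site sequences (T-box ``AGGTGTGG`` and the
    minus-strand GLI site ``GGACCACCCAGC``) at their published chr8
    offsets, padded with seeded random flanking sequence: the flanks are
    synthetic, only the two sites and their spacing are real.

    Returns ``(sequence, region_start_0based)`` so that plus-strand
    genomic coordinates are ``region_start + site.start``.
    """
    tbx_start0 = FOXF1A_TBX_SITE_START_1BASED - 1
    gli_start0 = FOXF1A_GLI_SITE_START_1BASED - 1
    region_start = tbx_start0 - flank
    region_end = gli_start0 + len(FOXF1A_GLI_SITE_SEQ) + flank
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = list("".join(rng.choice(bases, size=region_end - region_start)))
    for site_seq, start0 in (
        (FOXF1A_TBX_SITE_SEQ, tbx_start0),
        (FOXF1A_GLI_SITE_SEQ, gli_start0),
    ):
        off = start0 - region_start
        seq[off : off + len(site_seq)] = list(site_seq)
    return "".join(seq), region_start
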