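"""End-to-end orchestration: simulate -> expression -> annotate ->
integrate -> motifs, as one reproducible seeded run.

A single config dict (YAML on disk) drives every stage; the master seed
deterministically derives per-stage seeds, and the config hash and seed
are recorded in the report so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import expression as expr
from . import integrate as integ
from . import motifs as mot
from . import peaks as pk
from . import synthetic as syn
from .genome import write_gene_table

_SEED_MOD = 2**31


def default_config() -> dict:
    """Study-scale defaults: a 2 x 100-Mbp genome with 2,000 genes
    (mouse-like ~100 kbp/gene density scaled down 10x), 4 case vs 3
    control pooled arrays, 150 peaks (2/3 near planted-gene TSSs), and
    enhancer sequences carrying the GLI + T-box pair at 30 bp spacing."""
    return {
        "seed": 0,
        "genome": {
            "n_chrom": 2,
            "n_genes": 2000,
            "chrom_len": 100_000_000,
            "min_spacing": 5_000,
            "family_fractions": {"TF": 0.10, "FOX": 0.02},
        },
        "expression": {
            "n_case": 4,
            "n_ctrl": 3,
            "noise_sd": 0.25,
            "de": {"n_down": 50, "n_up": 25, "lfc_range": [2.0, 3.0]},
        },
        "peaks": {
            "n_peaks": 150,
            "frac_near_tss": 0.667,
            "near_window": 50_000,
            "peak_width": 500,
        },
        "motifs": {
            "seq_len": 500,
            "gap": 30,
            "frac_planted": 1.0,
            "motif_a": "GLI",
            "motif_b": "TBX",
        },
        "thresholds": {
            "q_max": 0.005,
            "min_abs_fc": 2.0,
            "n_perm": 100,
            "window": 100_000,
            "max_gap": 50,
            "max_mismatch": {"GLI": 2, "TBX": 0},
            "family_label": "TF",
            "sidedness": "one",
            "universe_n": None,
        },
    }


def load_config(path: str | Path) -> dict:
    """Read a YAML config and merge it over the defaults (per-stage deep
    merge, scalars override)."""
    user = yaml.safe_load(Path(path).read_text()) or {}
    return merge_config(user)


def merge_config(user: Mapping[str, Any]) -> dict:
    cfg = default_config()

    def _merge(base: dict, over: Mapping) -> dict:
        for k, v in over.items():
            if isinstance(v, Mapping) and isinstance(base.get(k), dict):
                _merge(base[k], v)
            else:
                base[k] = copy.deepcopy(v)
        return base

    return _merge(cfg, user or {})


def config_hash(cfg: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def derive_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(seed) * 1_000_003 + 7919 * stage + 1) % _SEED_MOD


def run_all(config: Mapping[str, Any] | None = None, outdir: str | Path | None = None) -> dict:
    """Run the full synthetic pipeline and return the run report.

    Stages run in dependency order; every output file is accompanied by
    the config hash and master seed in the report, and a rerun with the
    same config produces identical outputs.
    """
    cfg = merge_config(config or {})
    seed = int(cfg["seed"])
    chash = config_hash(cfg)
    report: dict[str, Any] = {"provenance": {"seed": seed, "config_hash": chash}}

    # --- simulate ---------------------------------------------------------
    gcfg = cfg["genome"]
    genome = syn.simulate_genome(
        n_chrom=gcfg["n_chrom"],
        n_genes=gcfg["n_genes"],
        chrom_len=gcfg["chrom_len"],
        family_fractions=gcfg.get("family_fractions"),
        min_spacing=gcfg.get("min_spacing", 5_000),
        seed=derive_seed(seed, 1),
    )
    ecfg = cfg["expression"]
    ds, truth_expr = syn.simulate_expression(
        genome,
        n_case=ecfg["n_case"],
        n_ctrl=ecfg["n_ctrl"],
        de_spec=ecfg.get("de"),
        noise_sd=ecfg.get("noise_sd", 0.25),
        seed=derive_seed(seed, 2),
    )
    down_genes = sorted(g for g, l in truth_expr.de_genes.items() if l < 0)
    pcfg = cfg["peaks"]
    peakset, truth_peaks = syn.simulate_peaks(
        genome,
        n_peaks=pcfg["n_peaks"],
        frac_near_tss=pcfg["frac_near_tss"],
        near_window=pcfg["near_window"],
        peak_width=pcfg["peak_width"],
        target_genes=down_genes or None,
        seed=derive_seed(seed, 3),
    )
    mcfg = cfg["motifs"]
    motif_a = mot.BUILTIN_MOTIFS[mcfg["motif_a"]]
    motif_b = mot.BUILTIN_MOTIFS[mcfg["motif_b"]]
    target_peak_ids = sorted(truth_peaks.target_peaks)
    seqs, truth_motifs = syn.plant_motif_pairs(
        n_seqs=len(target_peak_ids),
        seq_len=mcfg["seq_len"],
        motif_a=motif_a,
        motif_b=motif_b,
        gap=mcfg["gap"],
        frac_planted=mcfg["frac_planted"],
        seq_ids=target_peak_ids,
        seed=derive_seed(seed, 4),
    )
    report["simulate"] = {
        "n_genes": genome.n_genes,
        "n_planted_de": len(truth_expr.de_genes),
        "n_peaks": len(peakset),
        "n_target_peaks": len(target_peak_ids),
        "n_sequences": len(seqs),
    }

    # --- expression -------------------------------------------------------
    th = cfg["thresholds"]
    filtered, filter_report = expr.filter_probes(ds)
    norm = expr.normalize(filtered)
    res = expr.sam_test(norm, expr.SamParams(n_perm=th["n_perm"], seed=derive_seed(seed, 5)))
    sig = expr.select_signature(res, q_max=th["q_max"], min_abs_fc=th["min_abs_fc"])
    report["expression"] = {
        "filter": filter_report,
        "n_genes_tested": int(len(res)),
        "signature_size": len(sig),
        "s0": float(res.attrs["s0"]),
        "n_permutations": int(res.attrs["n_permutations"]),
    }

    # --- annotate ---------------------------------------------------------
    links = pk.annotate_peaks(peakset, genome, window=th["window"])
    bound_genes = sorted({ln.gene_id for ln in links})
    report["annotate"] = {
        "n_links": len(links),
        "n_bound_genes": len(bound_genes),
        "n_window_links": sum(1 for ln in links if ln.rule == "window"),
        "n_nearest_links": sum(1 for ln in links if ln.rule == "nearest"),
    }

    # --- integrate --------------------------------------------------------
    universe_n = th.get("universe_n") or genome.n_genes
    targets = integ.intersect_signature(links, sig)
    enrichments: dict[str, integ.EnrichmentResult] = {}
    if len(sig) and bound_genes:
        enrichments["signature_vs_bound"] = integ.enrichment_fet(
            sig.gene_ids(), bound_genes, universe_n, sidedness=th["sidedness"]
        )
    fam_label = th.get("family_label")
    if fam_label and genome.family_members(fam_label):
        enrichments[f"targets_vs_{fam_label}"] = integ.family_enrichment(
            targets, genome.family_map(), genome.gene_ids(), fam_label,
            sidedness=th["sidedness"],
        )
    planted_cotargets = {
        g for g in truth_peaks.target_peaks.values() if g in truth_expr.de_genes
    }
    recovered = targets.genes & planted_cotargets
    report["integrate"] = {
        "n_target_genes": targets.n_genes,
        "n_target_peaks": targets.n_peaks,
        "target_genes": sorted(targets.genes),
        "n_planted_cotargets": len(planted_cotargets),
        "cotarget_recall": (len(recovered) / len(planted_cotargets)) if planted_cotargets else None,
        "cotarget_precision": (len(recovered) / targets.n_genes) if targets.n_genes else None,
        "enrichments": {k: v.as_dict() for k, v in enrichments.items()},
    }

    # --- motifs -----------------------------------------------------------
    mm = th["max_mismatch"]
    sites_a: list[mot.MotifSite] = []
    sites_b: list[mot.MotifSite] = []
    for sid, s in seqs:
        sites_a += mot.scan_consensus(s, motif_a, max_mismatch=mm.get(motif_a.motif_id, 0), seq_id=sid)
        sites_b += mot.scan_consensus(s, motif_b, max_mismatch=mm.get(motif_b.motif_id, 0), seq_id=sid)
    pairs = mot.find_adjacent_pairs(sites_a, sites_b, max_gap=th["max_gap"])
    seqs_with_pair = {p.site_a.seq_id for p in pairs}
    planted_seqs = set(truth_motifs.motif_pairs)
    report["motifs"] = {
        "n_sites_a": len(sites_a),
        "n_sites_b": len(sites_b),
        "n_pairs": len(pairs),
        "n_sequences_with_pair": len(seqs_with_pair),
        "planted_pair_recall": (
            len(seqs_with_pair & planted_seqs) / len(planted_seqs) if planted_seqs else None
        ),
    }

    # --- consistency ------------------------------------------------------
    assert targets.n_genes <= len(sig) or len(sig) == 0
    fr = report["expression"]["filter"]
    assert (
        fr["removed_qc"] + fr["removed_spread"] + fr["removed_unannotated"]
        == fr["n_input"] - fr["n_retained"]
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_table(genome, outdir / "genome.tsv")
        pk.write_bed(peakset, outdir / "peaks.bed")
        expr.write_expression(
            ds, outdir / "matrix.tsv", outdir / "samples.tsv", outdir / "qc_flags.tsv"
        )
        mot.write_fasta(seqs, outdir / "sequences.fa")
        truth = syn.SyntheticTruth(
            de_genes=truth_expr.de_genes,
            target_peaks=truth_peaks.target_peaks,
            motif_pairs=truth_motifs.motif_pairs,
        )
        truth.to_json(outdir / "truth.json")
        expr.de_results_to_tsv(res, outdir / "de_results.tsv")
        expr.signature_to_tsv(sig, outdir / "signature.tsv")
        pk.links_to_tsv(links, outdir / "links.tsv")
        integ.targets_to_tsv(targets, outdir / "targets.tsv", de_table=res)
        integ.enrichments_to_tsv(enrichments, outdir / "enrichment.tsv")
        mot.sites_to_tsv(sites_a + sites_b, outdir / "motif_sites.tsv")
        mot.pairs_to_tsv(pairs, outdir / "motif_pairs.tsv")
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report
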