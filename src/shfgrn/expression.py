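"""Differential-expression signature construction for pooled case/control
microarray data.

The stages mirror standard two-colour-array practice for small pooled
designs (a handful of mutant vs wild-type RNA pools):

1. probe filtering (array QC flags, cross-sample spread, gene annotation),
2. per-array calibration followed by a generalized-log transform,
3. a SAM-type moderated t statistic ``d = (mean_case - mean_ctrl)/(s + s0)``
   with a permutation null over group-label assignments,
4. Q-value selection of the signature (default Q <= 0.005, |FC| >= 2),
5. a stringent three-test candidate filter (rank-sum p, permutation-t
   FDR, |FC| > 3),
6. sample clustering and hypergeometric gene-set over-representation.

With 4 cases vs 3 controls there are only C(7,4) = 35 distinct label
assignments; the permutation null is then enumerated exactly rather than
sampled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .integrate import EnrichmentResult, cross_product_odds_ratio


@dataclass
class ExpressionDataset:
    """Probe x sample intensities with group labels and QC flags.

    ``values`` is a probes-by-samples DataFrame; ``probe_map`` maps each
    probe to a gene id or ``None`` (unannotated); ``qc_flags`` is a
    boolean DataFrame aligned with ``values`` (True = pass); ``groups``
    maps each sample to ``"case"`` or ``"control"``.  ``scale`` flags
    whether values are raw intensities or transformed.
    """

    values: pd.DataFrame
    probe_map: dict
    groups: dict
    qc_flags: pd.DataFrame | None = None
    scale: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.qc_flags is None:
            self.qc_flags = pd.DataFrame(
                True, index=self.values.index, columns=self.values.columns
            )
        if not self.values.index.equals(self.qc_flags.index) or not self.values.columns.equals(
            self.qc_flags.columns
        ):
            raise ValueError("qc_flags must be aligned with the value matrix")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = {g for s, g in self.groups.items() if g not in ("case", "control")}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite intensities")
        if self.scale == "raw" and (vals < 0).any():
            raise ValueError("negative raw intensities")

    def sample_indices(self) -> tuple[list[int], list[int]]:
        samples = list(self.values.columns)
        case = [i for i, s in enumerate(samples) if self.groups[s] == "case"]
        ctrl = [i for i, s in enumerate(samples) if self.groups[s] == "control"]
        return case, ctrl


@dataclass
class SamParams:
    """Knobs for the permutation d-statistic."""

    n_perm: int = 100
    s0_quantile_grid: tuple = tuple(np.round(np.arange(0.0, 1.01, 0.05), 2))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if any(not (0.0 <= q <= 1.0) for q in self.s0_quantile_grid):
            raise ValueError("s0 quantile grid must lie in [0, 1]")


@dataclass
class GeneSignature:
    """Genes passing the differential-expression thresholds.

    ``genes`` maps gene id to direction in the case group ("up"/"down").
    """

    genes: dict
    q_max: float
    min_abs_fc: float

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def gene_ids(self) -> list[str]:
        return sorted(self.genes)


# ---------------------------------------------------------------------------
# probe filtering


def filter_probes(ds: ExpressionDataset) -> tuple[ExpressionDataset, dict]:
    """Retain probes that pass QC on all arrays, show above-median
    cross-sample spread, and map to an annotated gene.

    The spread criterion keeps probes whose across-sample IQR is at
    least the median IQR over all probes ("top half" of the spread
    distribution).  The IQR is measured on the log2 scale so that the
    criterion reflects relative spread rather than brightness, the usual
    convention for expression IQR filters.  The threshold is recorded in
    ``meta`` and reused on re-application, making the filter idempotent.
    Each removed probe is attributed to the first criterion it fails
    (QC, spread, annotation), so the per-criterion counts sum to the
    total removed.
    """
    if ds.scale != "raw":
        raise ValueError("filter_probes expects raw-scale intensities")
    vals = ds.values
    logged = np.log2(vals + 1.0)
    iqr = logged.quantile(0.75, axis=1) - logged.quantile(0.25, axis=1)
    threshold = ds.meta.get("iqr_threshold")
    if threshold is None:
        threshold = float(iqr.median())
    qc_pass = ds.qc_flags.all(axis=1)
    spread_pass = iqr >= threshold
    annotated = pd.Series(
        [ds.probe_map.get(p) is not None for p in vals.index], index=vals.index
    )

    removed_qc = int((~qc_pass).sum())
    removed_spread = int((qc_pass & ~spread_pass).sum())
    removed_unannot = int((qc_pass & spread_pass & ~annotated).sum())
    keep = qc_pass & spread_pass & annotated
    report = {
        "n_input": int(len(vals)),
        "removed_qc": removed_qc,
        "removed_spread": removed_spread,
        "removed_unannotated": removed_unannot,
        "n_retained": int(keep.sum()),
    }
    if report["n_retained"] == 0:
        raise ValueError(f"no probes survive filtering: {report}")
    kept = list(vals.index[keep])
    out = ExpressionDataset(
        values=vals.loc[kept].copy(),
        probe_map={p: ds.probe_map.get(p) for p in kept},
        groups=dict(ds.groups),
        qc_flags=ds.qc_flags.loc[kept].copy(),
        scale=ds.scale,
        meta={**ds.meta, "iqr_threshold": float(threshold)},
    )
    return out, report


# ---------------------------------------------------------------------------
# normalization


def normalize(ds: ExpressionDataset, glog_c: float | None = None) -> ExpressionDataset:
    """Per-array affine calibration followed by a generalized-log transform.

    Each array is rescaled so its median and IQR match the across-array
    medians of those statistics, then transformed with
    ``glog2(x) = log2(x + sqrt(x^2 + c^2)) - 1``, which is monotone,
    tolerates background-subtracted values near zero, and approaches
    plain ``log2`` for large intensities.  ``c`` defaults to the 5th
    percentile of the calibrated intensities.
    """
    if ds.scale != "raw":
        raise ValueError("normalize expects raw-scale intensities")
    vals = ds.values.to_numpy(dtype=float)
    med = np.median(vals, axis=0)
    q75 = np.quantile(vals, 0.75, axis=0)
    q25 = np.quantile(vals, 0.25, axis=0)
    spread = q75 - q25
    if np.any(spread <= 0):
        flat = [ds.values.columns[i] for i in np.nonzero(spread <= 0)[0]]
        raise ValueError(f"zero-spread array(s), cannot calibrate: {flat}")
    ref_med = float(np.median(med))
    ref_spread = float(np.median(spread))
    cal = (vals - med) / spread * ref_spread + ref_med
    if glog_c is None:
        pos = cal[cal > 0]
        glog_c = float(np.quantile(pos, 0.05)) if pos.size else 1.0
        glog_c = max(glog_c, 1e-8)
    trans = np.log2(cal + np.sqrt(cal**2 + glog_c**2)) - 1.0
    out = ExpressionDataset(
        values=pd.DataFrame(trans, index=ds.values.index, columns=ds.values.columns),
        probe_map=dict(ds.probe_map),
        groups=dict(ds.groups),
        qc_flags=ds.qc_flags.copy(),
        scale="glog2",
        meta={**ds.meta, "raw_values": ds.values.copy(), "glog_c": glog_c},
    )
    return out


# ---------------------------------------------------------------------------
# SAM statistic


def _group_stats(X: np.ndarray, case: Sequence[int], ctrl: Sequence[int]):
    """Mean difference and pooled standard error per row."""
    n1, n2 = len(case), len(ctrl)
    m1 = X[:, case].mean(axis=1)
    m2 = X[:, ctrl].mean(axis=1)
    ss = ((X[:, case] - m1[:, None]) ** 2).sum(axis=1) + (
        (X[:, ctrl] - m2[:, None]) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return m1 - m2, s


def _safe_ratio(r: np.ndarray, denom: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    nz = denom > 0
    out[nz] = r[nz] / denom[nz]
    # zero denominator with zero numerator -> 0 (flat probe); with
    # non-zero numerator -> large finite value of the right sign
    big = float(np.abs(out[nz]).max()) if nz.any() else 0.0
    lift = ~nz & (r != 0)
    out[lift] = np.sign(r[lift]) * max(big * 10, 1e6)
    return out


def choose_s0(r: np.ndarray, s: np.ndarray, quantile_grid: Sequence[float]) -> float:
    """SAM fudge factor: the s-quantile minimizing the coefficient of
    variation of the median absolute d across windows of s."""
    if np.all(s == 0):
        return 0.0
    candidates = np.quantile(s, np.asarray(quantile_grid))
    n_bins = min(10, max(2, len(s) // 20))
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, n_bins)
    best_s0, best_cv = float(candidates[0]), math.inf
    for s0 in candidates:
        d = _safe_ratio(r, s + s0)
        mads = np.array(
            [np.median(np.abs(d[idx] - np.median(d[idx]))) / 0.64 for idx in bins if idx.size]
        )
        mean = mads.mean()
        if mean <= 0:
            continue
        cv = mads.std() / mean
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _label_assignments(n: int, k: int, n_perm: int, seed: int) -> tuple[list[tuple], bool]:
    """Distinct case-label assignments: exhaustive when few, sampled
    without replacement otherwise."""
    total = math.comb(n, k)
    if total <= max(n_perm, 10_000):
        combos = list(itertools.combinations(range(n), k))
        if total <= n_perm:
            return combos, True
        rng = np.random.default_rng(seed)
        idx = rng.choice(total, size=n_perm, replace=False)
        return [combos[i] for i in idx], False
    rng = np.random.default_rng(seed)
    seen: set[tuple] = set()
    while len(seen) < n_perm:
        seen.add(tuple(sorted(rng.choice(n, size=k, replace=False).tolist())))
    return sorted(seen), False


def sam_test(ds: ExpressionDataset, params: SamParams | None = None) -> pd.DataFrame:
    """Per-gene SAM-style differential-expression statistics.

    Returns a DataFrame indexed by gene id with columns ``probe_id, fc,
    log2fc, d, perm_p, q, wilcoxon_p, emp_t_fdr``.  Statistics are
    computed per probe and collapsed to genes by the probe with the
    largest |d|.  ``perm_p`` is the pooled permutation p; ``q`` is the
    SAM-style permutation FDR (median null exceedance count over label
    assignments, null-proportion scaled, monotone-enforced in |d|).
    Fold change is the linear case/control ratio of raw group means when
    the raw matrix is available.
    """
    params = params or SamParams()
    case, ctrl = ds.sample_indices()
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need at least 2 samples per group")
    X = ds.values.to_numpy(dtype=float)
    n = X.shape[1]
    probes = list(ds.values.index)

    r, s = _group_stats(X, case, ctrl)
    s0 = choose_s0(r, s, params.s0_quantile_grid)
    d = _safe_ratio(r, s + s0)
    t = _safe_ratio(r, s)

    combos, exact = _label_assignments(n, len(case), params.n_perm, params.seed)
    all_idx = set(range(n))
    null_d_parts = []
    null_signed_parts = []
    null_t_sorted = []
    for combo in combos:
        c_idx = list(combo)
        k_idx = sorted(all_idx - set(combo))
        rp, sp = _group_stats(X, c_idx, k_idx)
        dp = _safe_ratio(rp, sp + s0)
        null_signed_parts.append(dp)
        null_d_parts.append(np.abs(dp))
        null_t_sorted.append(np.sort(np.abs(_safe_ratio(rp, sp))))
    null_d = np.sort(np.concatenate(null_d_parts))

    abs_d = np.abs(d)
    cnt_ge = null_d.size - np.searchsorted(null_d, abs_d, side="left")
    if exact:
        perm_p = cnt_ge / null_d.size
    else:
        perm_p = (1 + cnt_ge) / (1 + null_d.size)

    # SAM-style permutation FDR on |d|: at each observed threshold, the
    # median over label assignments of the null exceedance count, scaled
    # by a null-proportion estimate, over the observed count.  The median
    # keeps the single truth-aligned assignment from flooring the FDR at
    # 1/#assignments.
    obs_d_sorted = np.sort(abs_d)
    r_d = abs_d.size - np.searchsorted(obs_d_sorted, abs_d, side="left")
    null_counts_d = np.stack(
        [
            nd.size - np.searchsorted(nd, abs_d, side="left")
            for nd in (np.sort(p) for p in null_d_parts)
        ]
    )
    fp_d = np.median(null_counts_d, axis=0)
    signed_null = np.concatenate([p for p in null_signed_parts])
    q25, q75 = np.quantile(signed_null, [0.25, 0.75])
    n_mid = int(np.sum((d >= q25) & (d <= q75)))
    pi0 = min(1.0, max(n_mid / (0.5 * abs_d.size), 0.0)) if abs_d.size else 1.0
    fdr_d = np.minimum(1.0, pi0 * fp_d / np.maximum(r_d, 1))
    # q-value: minimum FDR over all thresholds at least as strict
    order_desc = np.argsort(-abs_d, kind="stable")
    q_d = np.empty_like(fdr_d)
    q_d[order_desc] = np.minimum.accumulate(fdr_d[order_desc])

    # permutation-t FDR: median over label assignments of the null count
    # at each observed |t| threshold, over the observed count
    abs_t = np.abs(t)
    obs_sorted = np.sort(abs_t)
    obs_ge = abs_t.size - np.searchsorted(obs_sorted, abs_t, side="left")
    null_counts = np.stack(
        [nt.size - np.searchsorted(nt, abs_t, side="left") for nt in null_t_sorted]
    )
    fp = np.median(null_counts, axis=0)
    emp_t_fdr = np.minimum(1.0, fp / np.maximum(obs_ge, 1))

    wilcoxon_p = np.ones(len(probes))
    case_vals = X[:, case]
    ctrl_vals = X[:, ctrl]
    for i in range(len(probes)):
        if np.all(case_vals[i] == case_vals[i][0]) and np.all(
            ctrl_vals[i] == ctrl_vals[i][0]
        ) and case_vals[i][0] == ctrl_vals[i][0]:
            wilcoxon_p[i] = 1.0
            continue
        wilcoxon_p[i] = stats.mannwhitneyu(
            case_vals[i], ctrl_vals[i], alternative="two-sided", method="auto"
        ).pvalue

    raw = ds.meta.get("raw_values")
    if raw is not None:
        raw_np = raw.loc[probes].to_numpy(dtype=float)
        mc = raw_np[:, case].mean(axis=1)
        mk = raw_np[:, ctrl].mean(axis=1)
    elif ds.scale == "raw":
        mc = X[:, case].mean(axis=1)
        mk = X[:, ctrl].mean(axis=1)
    else:
        # fall back to back-transformed log-scale difference
        mc = np.exp2(X[:, case].mean(axis=1))
        mk = np.exp2(X[:, ctrl].mean(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mk > 0, mc / np.maximum(mk, 1e-300), np.inf)
    fc = np.maximum(fc, 1e-300)

    probe_table = pd.DataFrame(
        {
            "probe_id": probes,
            "gene_id": [ds.probe_map.get(p) for p in probes],
            "fc": fc,
            "log2fc": np.log2(fc),
            "d": d,
            "perm_p": perm_p,
            "q": q_d,
            "wilcoxon_p": wilcoxon_p,
            "emp_t_fdr": emp_t_fdr,
        }
    )
    annotated = probe_table[probe_table["gene_id"].notna()].copy()
    if annotated.empty:
        raise ValueError("no annotated probes in the dataset")
    annotated["abs_d"] = annotated["d"].abs()
    annotated.sort_values(["abs_d", "probe_id"], ascending=[False, True], inplace=True)
    collapsed = annotated.drop_duplicates("gene_id", keep="first").set_index("gene_id")
    collapsed = collapsed.sort_index()
    cols = ["probe_id", "fc", "log2fc", "d", "perm_p", "q", "wilcoxon_p", "emp_t_fdr"]
    res = collapsed[cols]
    res.attrs["s0"] = s0
    res.attrs["pi0"] = pi0
    res.attrs["n_permutations"] = len(combos)
    res.attrs["exact_permutations"] = exact
    return res


def storey_qvalues(p: np.ndarray, lambdas: Sequence[float] | None = None) -> np.ndarray:
    """Storey Q-values with a plateau pi0 estimate, falling back to
    Benjamini-Hochberg (pi0 = 1) when the estimate is unstable."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p
    if lambdas is None:
        lambdas = np.arange(0.05, 0.90, 0.05)
    ests = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    tail = ests[-5:] if ests.size >= 5 else ests
    pi0 = float(np.mean(tail))
    if not np.isfinite(pi0) or pi0 <= 0:
        pi0 = 1.0
    pi0 = min(pi0, 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1] * pi0
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# selection


def select_signature(
    res: pd.DataFrame, q_max: float = 0.005, min_abs_fc: float = 2.0
) -> GeneSignature:
    """Signature genes: Q <= q_max and linear fold change >= min_abs_fc
    or <= 1/min_abs_fc, with the direction of change recorded."""
    genes: dict[str, str] = {}
    for gene_id, row in res.iterrows():
        if row["q"] <= q_max and (row["fc"] >= min_abs_fc or row["fc"] <= 1.0 / min_abs_fc):
            genes[gene_id] = "up" if row["fc"] >= 1.0 else "down"
    return GeneSignature(genes=genes, q_max=q_max, min_abs_fc=min_abs_fc)


def stringent_candidates(
    res: pd.DataFrame,
    wilcoxon_max: float = 0.15,
    emp_fdr_max: float = 0.1,
    min_abs_fc: float = 3.0,
) -> list[str]:
    """Candidates passing all three stringent tests (rank-sum p,
    permutation-t FDR, |FC| > 3), sorted by |log2FC| descending."""
    for col in ("wilcoxon_p", "emp_t_fdr", "fc"):
        if col not in res.columns:
            raise ValueError(f"missing statistic column {col!r}")
    mask = (
        (res["wilcoxon_p"] < wilcoxon_max)
        & (res["emp_t_fdr"] < emp_fdr_max)
        & ((res["fc"] > min_abs_fc) | (res["fc"] < 1.0 / min_abs_fc))
    )
    hits = res[mask].copy()
    hits["abs_log2fc"] = hits["log2fc"].abs()
    hits.sort_values(["abs_log2fc"], ascending=False, inplace=True, kind="stable")
    return list(hits.index)


# ---------------------------------------------------------------------------
# clustering and gene-set tests


def cluster_samples(ds: ExpressionDataset, genes: Iterable[str]):
    """Agglomerative clustering of sample columns restricted to the
    probes of the given genes; returns (linkage matrix, 2-cut labels)."""
    geneset = set(genes)
    probes = [p for p in ds.values.index if ds.probe_map.get(p) in geneset]
    if len(ds.values.columns) < 2:
        raise ValueError("need at least 2 samples to cluster")
    if not probes:
        raise ValueError("no probes map to the requested genes")
    M = ds.values.loc[probes].to_numpy(dtype=float)
    dist = pdist(M.T, metric="euclidean")
    Z = hierarchy.linkage(dist, method="average")
    labels = hierarchy.fcluster(Z, 2, criterion="maxclust")
    return Z, dict(zip(ds.values.columns, (int(v) for v in labels)))


def geneset_enrichment(
    sig, gene_sets: Mapping[str, Iterable[str]], universe: Iterable[str]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of the signature in
    each gene set, BH-adjusted across sets."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sig_genes = set(sig.genes) if hasattr(sig, "genes") else set(sig)
    sig_genes &= uni
    rows = []
    for set_id, members in gene_sets.items():
        B = set(members) & uni
        a = len(sig_genes & B)
        b = len(sig_genes) - a
        c = len(B) - a
        d = len(uni) - len(sig_genes) - len(B) + a
        p = float(stats.hypergeom.sf(a - 1, len(uni), len(B), len(sig_genes)))
        rows.append(
            {
                "set_id": set_id,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": cross_product_odds_ratio(a, b, c, d),
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("set_id")
    if len(out):
        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out.sort_values("p", inplace=True, kind="stable")
    return out


# ---------------------------------------------------------------------------
# i/o


def write_expression(
    ds: ExpressionDataset,
    matrix_path: str | Path,
    samples_path: str | Path,
    qc_path: str | Path | None = None,
) -> None:
    """Write the matrix (probe_id, gene_id, samples...), the sample sheet
    (sample_id, group), and optionally the QC flag matrix."""
    mat = ds.values.copy()
    mat.insert(0, "gene_id", [ds.probe_map.get(p) or "." for p in mat.index])
    mat.index.name = "probe_id"
    mat.to_csv(matrix_path, sep="\t")
    with Path(samples_path).open("w") as fh:
        fh.write("sample_id\tgroup\n")
        for s in ds.values.columns:
            fh.write(f"{s}\t{ds.groups[s]}\n")
    if qc_path is not None:
        flags = ds.qc_flags.astype(int)
        flags.index.name = "probe_id"
        flags.to_csv(qc_path, sep="\t")


def read_expression(
    matrix_path: str | Path,
    samples_path: str | Path,
    qc_path: str | Path | None = None,
    scale: str = "raw",
) -> ExpressionDataset:
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if "gene_id" not in mat.columns:
        raise ValueError(f"{matrix_path}: missing gene_id column")
    gene_col = mat.pop("gene_id")
    probe_map = {p: (None if g == "." else g) for p, g in gene_col.items()}
    samples = pd.read_csv(samples_path, sep="\t")
    groups = dict(zip(samples["sample_id"], samples["group"]))
    qc = None
    if qc_path is not None:
        qc = pd.read_csv(qc_path, sep="\t", index_col=0).astype(bool)
        qc = qc.loc[mat.index, mat.columns]
    return ExpressionDataset(
        values=mat.astype(float), probe_map=probe_map, groups=groups, qc_flags=qc, scale=scale
    )


def de_results_to_tsv(res: pd.DataFrame, path: str | Path) -> None:
    out = res.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def signature_to_tsv(sig: GeneSignature, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tdirection\n")
        for g in sorted(sig.genes):
            fh.write(f"{g}\t{sig.genes[g]}\n")


def read_signature_tsv(path: str | Path, q_max: float = float("nan"), min_abs_fc: float = float("nan")) -> GeneSignature:
    genes: dict[str, str] = {}
    with Path(path).open() as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            gene_id, direction = line.rstrip("\n").split("\t")[:2]
            genes[gene_id] = direction
    return GeneSignature(genes=genes, q_max=q_max, min_abs_fc=min_abs_fc)
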