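"""Bump-hunting differentially methylated regions with a permutation null.

Per probe, methylation M-values (logit-2 of beta) are regressed on a
subtype-vs-rest indicator; the coefficients are smoothed within probe
clusters (same chromosome, inter-probe gaps <= 500 bp) by a running mean,
and candidate regions are maximal same-sign runs of smoothed coefficients
exceeding a cutoff chosen as a quantile of the pooled permutation
distribution of |smoothed coefficients|. Region inference is family-level:
the area statistic (sum of |smoothed coefficients|) is compared against the
pooled null areas from label permutations.

Hyper/hypo classification uses the beta-scale group difference with
asymmetric thresholds: hyper-methylated when beta_diff >= 0.2, hypo when
beta_diff <= 0 (both at permutation p <= 0.05); the gap in between is
reported unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lncstrat.annotation import GeneModel, GenomicRegionLabel, classify_position

BETA_EPS = 1e-3
MAXGAP_DEFAULT = 500
CUTOFF_Q_DEFAULT = 0.95
B_DEFAULT = 1000
HYPER_MIN_DEFAULT = 0.2
P_MAX_DEFAULT = 0.05


def beta_to_m(beta, eps: float = BETA_EPS):
    """M = log2(beta / (1 - beta)) after clamping beta to [eps, 1 - eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    out = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    return out


def filter_variant_quartile(M: pd.DataFrame) -> pd.DataFrame:
    """Keep the most variant quartile of probes: exactly ceil(n/4) rows
    with the largest row variances; ties broken by row order."""
    n = len(M)
    k = int(np.ceil(n / 4))
    var = M.var(axis=1, ddof=1).to_numpy()
    if np.allclose(var, 0.0):
        warnings.warn("all probes have zero variance; keeping first ceil(n/4) by id")
    order = np.argsort(-var, kind="stable")[:k]
    keep = np.zeros(n, dtype=bool)
    keep[order] = True
    return M.loc[keep]


def cluster_probes(manifest: pd.DataFrame, maxgap: int = MAXGAP_DEFAULT) -> list:
    """Group probes into clusters: same chromosome, successive gaps <= maxgap.

    Returns a list of probe-id lists, ordered by (chrom, position).
    """
    df = manifest.sort_values(["chrom", "pos"], kind="stable")
    clusters = []
    cur: list = []
    prev_chrom, prev_pos = None, None
    for pid, chrom, pos in zip(df["probe_id"], df["chrom"], df["pos"]):
        if cur and chrom == prev_chrom and pos - prev_pos <= maxgap:
            cur.append(pid)
        else:
            if cur:
                clusters.append(cur)
            cur = [pid]
        prev_chrom, prev_pos = chrom, pos
    if cur:
        clusters.append(cur)
    return clusters


@dataclass
class DMRegion:
    """A contiguous probe run with a coherent methylation difference."""

    chrom: str
    start: int
    end: int
    probe_ids: list
    value: float          # mean smoothed group coefficient (M scale)
    area: float           # sum of |smoothed coefficients|
    p_perm: float = np.nan        # family-level (max-area) permutation p
    p_area: float = np.nan        # pooled-tail permutation p over null areas
    beta_diff: float = np.nan
    direction: str | None = None
    category: str | None = None
    gene_id: str | None = None
    is_lnc: bool = False

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def _smooth_within_clusters(arr: np.ndarray, cluster_ids: np.ndarray,
                            window: int) -> np.ndarray:
    """Centered running mean of width ``window`` that never crosses a
    cluster boundary; clusters shorter than ``window`` stay unsmoothed.
    ``arr`` is (..., n_probes)."""
    if window <= 1:
        return arr.copy()
    h = window // 2
    n = arr.shape[-1]
    # cluster lengths per position
    _, inv, counts = np.unique(cluster_ids, return_inverse=True, return_counts=True)
    clen = counts[inv]
    smooth_pos = clen >= window
    acc = arr.copy()
    cnt = np.ones(n)
    for off in range(1, h + 1):
        for sgn in (-1, 1):
            idx = np.arange(n) + sgn * off
            valid = (idx >= 0) & (idx < n)
            idx_c = np.clip(idx, 0, n - 1)
            valid &= cluster_ids[idx_c] == cluster_ids
            acc = acc + np.where(valid, arr[..., idx_c], 0.0)
            cnt = cnt + valid
    sm = acc / cnt
    return np.where(smooth_pos, sm, arr)


def _find_runs(row: np.ndarray, cutoff: float, cluster_ids: np.ndarray):
    """Maximal same-sign runs with |value| > cutoff inside one cluster.
    Yields (start_idx, end_idx_exclusive)."""
    key = np.where(np.abs(row) > cutoff, np.sign(row), 0.0)
    n = len(key)
    if n == 0:
        return []
    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = (key[1:] != key[:-1]) | (cluster_ids[1:] != cluster_ids[:-1])
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], n)
    return [(s, e) for s, e in zip(starts, ends) if key[s] != 0.0]


def bumphunt(M: pd.DataFrame, group, manifest: pd.DataFrame,
             cutoff_q: float = CUTOFF_Q_DEFAULT, B: int = B_DEFAULT,
             seed: int | None = None, maxgap: int = MAXGAP_DEFAULT,
             smooth_window: int = 3):
    """Detect candidate DMRs on the M-value matrix.

    ``group`` is a boolean per sample (subtype = True, rest = False),
    aligned with the columns of ``M``. Returns ``(regions, cutoff)`` where
    each region's ``p_perm`` is the family-level permutation p-value
    (1 + #{null areas >= observed area}) / (1 + total null areas).
    """
    g = np.asarray(group, dtype=bool)
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    man = manifest.set_index("probe_id").loc[M.index].rename_axis("probe_id")
    order = np.lexsort((man["pos"].to_numpy(), man["chrom"].to_numpy()))
    M = M.iloc[order]
    man = man.iloc[order]
    clusters = cluster_probes(man.reset_index(), maxgap=maxgap)
    cid_of = {}
    for ci, pids in enumerate(clusters):
        for pid in pids:
            cid_of[pid] = ci
    cluster_ids = np.array([cid_of[p] for p in M.index])

    Y = M.to_numpy(dtype=float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    x = g.astype(float)
    xc = x - x.mean()
    ssx = float(xc @ xc)
    beta_obs = (Yc @ xc) / ssx
    sm_obs = _smooth_within_clusters(beta_obs, cluster_ids, smooth_window)

    pos = man["pos"].to_numpy()
    chrom = man["chrom"].to_numpy()

    if B > 0:
        rng = np.random.default_rng(seed)
        perms = np.stack([rng.permutation(x) for _ in range(B)])
        perms_c = perms - perms.mean(axis=1, keepdims=True)
        beta_perm = (perms_c @ Yc.T) / ssx          # B x n_probes
        sm_perm = _smooth_within_clusters(beta_perm, cluster_ids, smooth_window)
        cutoff = float(np.quantile(np.abs(sm_perm), cutoff_q))
        null_areas = []
        null_max = np.zeros(B)
        for b in range(B):
            best = 0.0
            for s, e in _find_runs(sm_perm[b], cutoff, cluster_ids):
                a = float(np.abs(sm_perm[b, s:e]).sum())
                null_areas.append(a)
                best = max(best, a)
            null_max[b] = best
        null_areas = np.sort(np.asarray(null_areas))
    else:
        warnings.warn("B=0: regions returned with p_perm = NA")
        cutoff = float(np.quantile(np.abs(sm_obs), cutoff_q))
        null_areas = None
        null_max = None

    regions = []
    for s, e in _find_runs(sm_obs, cutoff, cluster_ids):
        seg = sm_obs[s:e]
        area = float(np.abs(seg).sum())
        if null_areas is not None:
            # family-level inference: the area is referred to the
            # per-permutation maximum null area, so the chance of any
            # null region reaching p_perm <= alpha is ~alpha; the pooled
            # tail over all null candidate areas is kept as p_area
            p = (1.0 + float(np.sum(null_max >= area))) / (1.0 + B)
            p_area = (1.0 + float(np.sum(null_areas >= area))) / (1.0 + len(null_areas))
        else:
            p = np.nan
            p_area = np.nan
        regions.append(DMRegion(
            chrom=str(chrom[s]), start=int(pos[s]), end=int(pos[e - 1]),
            probe_ids=list(M.index[s:e]), value=float(seg.mean()), area=area,
            p_perm=p, p_area=p_area,
        ))
    return regions, cutoff


def classify_dmrs(regions, beta: pd.DataFrame, group,
                  p_max: float = P_MAX_DEFAULT,
                  hyper_min: float = HYPER_MIN_DEFAULT):
    """Attach beta-scale group differences and hyper/hypo direction.

    hyper: beta_diff >= hyper_min and p_perm <= p_max; hypo: beta_diff <= 0
    and p_perm <= p_max; 0 < beta_diff < hyper_min at significant p is
    'unclassified'; non-significant regions get direction 'ns'.
    """
    g = np.asarray(group, dtype=bool)
    for r in regions:
        sub = beta.loc[r.probe_ids]
        r.beta_diff = float(sub.loc[:, g].to_numpy().mean()
                            - sub.loc[:, ~g].to_numpy().mean())
        if not (r.p_perm <= p_max):
            r.direction = "ns"
        elif r.beta_diff >= hyper_min:
            r.direction = "hyper"
        elif r.beta_diff <= 0:
            r.direction = "hypo"
        else:
            r.direction = "unclassified"
    return regions


def annotate_dmrs(regions, genes):
    """Label each region by its midpoint position relative to the genes.

    promoter-TSS of a lncRNA, gene body (exon/intron/TTS) of a lncRNA, or
    retained-but-flagged otherwise (``is_lnc`` False).
    """
    by_id = {g.gene_id: g for g in genes}
    for r in regions:
        mid = (r.start + r.end) // 2
        label = classify_position(r.chrom, mid, genes)
        r.category = label.category
        r.gene_id = label.gene_id
        r.is_lnc = (label.gene_id is not None
                    and by_id[label.gene_id].biotype == "lncRNA")
    return regions


def regions_to_frame(regions) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "n_probes": r.n_probes, "value": r.value, "area": r.area,
            "p_perm": r.p_perm, "p_area": r.p_area, "beta_diff": r.beta_diff,
            "direction": r.direction, "category": r.category,
            "gene_id": r.gene_id, "is_lnc": r.is_lnc,
            "probe_ids": ",".join(r.probe_ids),
        }
        for r in regions
    ]
    cols = ["chrom", "start", "end", "n_probes", "value", "area", "p_perm",
            "p_area", "beta_diff", "direction", "category", "gene_id", "is_lnc",
            "probe_ids"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class DMRResults:
    """Results of a bump-hunting fit: candidate regions, the permutation
    cutoff, and the parameters used."""

    regions: list
    cutoff: float
    B: int
    cutoff_q: float
    n_probes: int
    subtype: str = ""

    @property
    def table(self) -> pd.DataFrame:
        return regions_to_frame(self.regions)

    def significant(self, p_max: float = P_MAX_DEFAULT):
        return [r for r in self.regions if r.p_perm <= p_max]

    def summary(self) -> str:
        t = self.table
        sig = t["p_perm"] <= P_MAX_DEFAULT
        return "\n".join([
            f"Bump-hunting DMRs: {self.subtype or 'group contrast'}",
            f"  probes analyzed:   {self.n_probes}",
            f"  permutations (B):  {self.B}",
            f"  cutoff (q={self.cutoff_q:g}): {self.cutoff:.4g}",
            f"  candidate regions: {len(t)}",
            f"  significant (p<={P_MAX_DEFAULT:g}): {int(sig.sum())} "
            f"({int((sig & (t['direction'] == 'hyper')).sum())} hyper, "
            f"{int((sig & (t['direction'] == 'hypo')).sum())} hypo)",
        ])


class BumpHunter:
    """Model object for subtype-vs-rest DMR detection on beta values.

    Transforms beta to M-values, optionally keeps the most variant quartile
    of probes, and runs bump hunting with a permutation null. ``fit(seed)``
    returns :class:`DMRResults` with classified, annotated regions when
    ``genes`` is provided.
    """

    def __init__(self, beta: pd.DataFrame, manifest: pd.DataFrame, group,
                 cutoff_q: float = CUTOFF_Q_DEFAULT, B: int = B_DEFAULT,
                 maxgap: int = MAXGAP_DEFAULT, smooth_window: int = 3,
                 variant_quartile: bool = True, subtype: str = ""):
        self.beta = beta
        self.manifest = manifest
        self.group = np.asarray(group, dtype=bool)
        if len(self.group) != beta.shape[1]:
            raise ValueError("group length must match number of samples")
        self.cutoff_q = cutoff_q
        self.B = B
        self.maxgap = maxgap
        self.smooth_window = smooth_window
        self.variant_quartile = variant_quartile
        self.subtype = subtype

    def fit(self, seed: int | None = None, genes=None,
            p_max: float = P_MAX_DEFAULT,
            hyper_min: float = HYPER_MIN_DEFAULT) -> DMRResults:
        M = beta_to_m(self.beta)
        if self.variant_quartile:
            M = filter_variant_quartile(M)
        regions, cutoff = bumphunt(M, self.group, self.manifest,
                                   cutoff_q=self.cutoff_q, B=self.B, seed=seed,
                                   maxgap=self.maxgap,
                                   smooth_window=self.smooth_window)
        classify_dmrs(regions, self.beta, self.group, p_max=p_max,
                      hyper_min=hyper_min)
        if genes is not None:
            annotate_dmrs(regions, genes)
        return DMRResults(regions=regions, cutoff=cutoff, B=self.B,
                          cutoff_q=self.cutoff_q, n_probes=len(M),
                          subtype=self.subtype)
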