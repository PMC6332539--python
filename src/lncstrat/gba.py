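"""Guilt-by-association functional inference for lncRNAs.

Differentially expressed lncRNAs are correlated (Pearson, on
log2(FPKM + 1) across all cohort samples) with their cis (TSS distance
<= 100 kb) and trans (> 100 kb, same chromosome) protein-coding partners.
Partners passing r >= 0.55 and two-tailed p <= 0.05 feed a hypergeometric
gene-set enrichment against the background of all protein-coding genes.
The partner filter is one-sided positive by default (co-expressed partners
tend toward positive correlation); ``absolute=True`` admits |r| >= 0.55.
No multiple-testing correction is applied to enrichment p-values; BH q is
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lncstrat._stats import bh_adjust, hypergeom_sf_inclusive, pearson_with_p
from lncstrat.annotation import CIS_WINDOW_BP, assign_neighbors

R_MIN_DEFAULT = 0.55
P_MAX_DEFAULT = 0.05

__all__ = [
    "pearson_with_p", "build_neighbor_map", "correlate_partners", "enrich",
    "gba_report", "EnrichmentResult",
]


def build_neighbor_map(lnc_ids, genes, window_bp: int = CIS_WINDOW_BP) -> dict:
    """Map each lncRNA id to its [(pc_id, distance, relation)] partners."""
    by_id = {g.gene_id: g for g in genes}
    pcs = [g for g in genes if g.biotype == "protein_coding"]
    out = {}
    for lid in lnc_ids:
        lnc = by_id.get(lid)
        if lnc is None:
            continue
        cis, trans = assign_neighbors(lnc, pcs, window_bp=window_bp)
        out[lid] = ([(pc.gene_id, d, "cis") for pc, d in cis]
                    + [(pc.gene_id, d, "trans") for pc, d in trans])
    return out


def correlate_partners(
    fpkm: pd.DataFrame,
    de_lncs,
    neighbor_map: dict,
    r_min: float = R_MIN_DEFAULT,
    p_max: float = P_MAX_DEFAULT,
    log_transform: bool = True,
    absolute: bool = False,
) -> pd.DataFrame:
    """One association record per (DE lncRNA, same-chromosome PC partner).

    Expression vectors are log2(FPKM + 1) across all cohort samples
    (``log_transform=False`` uses raw FPKM). Zero-variance vectors yield
    flagged NA records that never count as significant.
    """
    expr = np.log2(fpkm + 1.0) if log_transform else fpkm
    rows = []
    for lid in de_lncs:
        if lid not in neighbor_map or lid not in expr.index:
            continue
        x = expr.loc[lid].to_numpy()
        for pc, dist, relation in neighbor_map[lid]:
            if pc not in expr.index:
                continue
            r, p = pearson_with_p(x, expr.loc[pc].to_numpy())
            if np.isnan(r):
                sig = False
            else:
                passes_r = abs(r) >= r_min if absolute else r >= r_min
                sig = bool(passes_r and p <= p_max)
            rows.append((lid, pc, relation, dist, r, p, sig))
    return pd.DataFrame(
        rows, columns=["lnc_id", "pc_id", "relation", "distance_bp", "r", "p",
                       "significant"],
    )


@dataclass
class EnrichmentResult:
    """Hypergeometric gene-set enrichment for one set."""

    set_name: str
    n_hits: int
    n_set: int
    n_selected: int
    n_background: int
    p_hyper: float
    member_hits: list
    significant: bool = False
    reportable: bool = False


def enrich(selected_genes, gene_sets: dict, background,
           p_max: float = P_MAX_DEFAULT, min_hits_reportable: int = 2) -> list:
    """Hypergeometric enrichment of ``selected_genes`` in each gene set.

    p = P(X >= hits) for X ~ Hypergeometric(N = |background|,
    K = |set ∩ background|, n = |selected|). ``significant`` flags
    p <= p_max; ``reportable`` additionally requires hits > 2 (the
    reporting rule for pathway tables). Results sorted by p.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    selected = set(selected_genes)
    if not selected <= background:
        extra = sorted(selected - background)[0]
        raise ValueError(f"selected gene {extra} not in background")
    N, n = len(background), len(selected)
    out = []
    for name, members in gene_sets.items():
        if isinstance(members, tuple):  # (description, members) from GMT reader
            members = members[1]
        kset = set(members) & background
        hits = sorted(kset & selected)
        p = hypergeom_sf_inclusive(len(hits), N, len(kset), n)
        out.append(EnrichmentResult(
            set_name=name, n_hits=len(hits), n_set=len(kset), n_selected=n,
            n_background=N, p_hyper=p, member_hits=hits,
            significant=p <= p_max,
            reportable=(p <= p_max and len(hits) > min_hits_reportable),
        ))
    out.sort(key=lambda r: (r.p_hyper, r.set_name))
    return out


def enrichment_frame(results) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"set_name": r.set_name, "n_hits": r.n_hits, "n_set": r.n_set,
             "n_selected": r.n_selected, "n_background": r.n_background,
             "p_hyper": r.p_hyper, "significant": r.significant,
             "reportable": r.reportable, "member_hits": ",".join(r.member_hits)}
            for r in results
        ],
        columns=["set_name", "n_hits", "n_set", "n_selected", "n_background",
                 "p_hyper", "significant", "reportable", "member_hits"],
    )
    if len(df):
        df["q_bh"] = bh_adjust(df["p_hyper"].to_numpy())
    else:
        df["q_bh"] = []
    return df


def gba_report(
    fpkm: pd.DataFrame,
    genes,
    de_lnc_ids,
    gene_sets: dict,
    mode: str = "cis",
    window_bp: int = CIS_WINDOW_BP,
    r_min: float = R_MIN_DEFAULT,
    p_max: float = P_MAX_DEFAULT,
    log_transform: bool = True,
    absolute: bool = False,
):
    """Full guilt-by-association pipeline for one DE lncRNA set.

    assign_neighbors -> correlate_partners (restricted to ``mode``) ->
    enrich against the all-protein-coding background. Returns
    ``(associations, enrichment_table, lnc_pathway_map)`` where the map
    gives, per gene set, the lncRNAs whose significant partners hit it
    (the lncRNA-based pathway assignment).
    """
    if mode not in {"cis", "trans"}:
        raise ValueError("mode must be 'cis' or 'trans'")
    nmap = build_neighbor_map(de_lnc_ids, genes)
    nmap = {k: [t for t in v if t[2] == mode] for k, v in nmap.items()}
    assoc = correlate_partners(fpkm, de_lnc_ids, nmap, r_min=r_min, p_max=p_max,
                               log_transform=log_transform, absolute=absolute)
    background = [g.gene_id for g in genes if g.biotype == "protein_coding"]
    selected = sorted(assoc.loc[assoc["significant"], "pc_id"].unique())
    results = enrich(selected, gene_sets, background, p_max=p_max)
    table = enrichment_frame(results)
    sig_assoc = assoc.loc[assoc["significant"]]
    lnc_map = {}
    for r in results:
        hits = set(r.member_hits)
        lncs = sorted(sig_assoc.loc[sig_assoc["pc_id"].isin(hits), "lnc_id"].unique())
        lnc_map[r.set_name] = lncs
    return assoc, table, lnc_map
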