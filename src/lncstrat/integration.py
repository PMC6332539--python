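"""Cross-omics integration: epigenetically altered lncRNAs and
chromatin-state enrichment.

An epigenetically altered lncRNA is one that is, in the same subtype,
(i) differentially methylated at its promoter, (ii) differentially
expressed, and (iii) shows a significant Pearson correlation between its
per-sample promoter methylation (log2-transformed mean beta over the
region's probes) and its expression (log2(FPKM + 1)). The correlation sign
is reported rather than hard-filtered; a ``concordant`` flag marks the
canonical promoter pattern (hypo-methylated & up-regulated, or
hyper-methylated & down-regulated).

Intronic/intergenic differentially methylated lncRNAs are tested for
enrichment of chromatin states of interest (Enhancer, Insulator by
default) against non-DM background lncRNAs with a two-sided Fisher exact
test computed by fixed-margin enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lncstrat._stats import fisher_exact_two_sided, pearson_with_p

BETA_EPS = 1e-3
P_MAX_DEFAULT = 0.05
STATES_OF_INTEREST = frozenset({"Enhancer", "Insulator"})


@dataclass
class EpiAlteredRecord:
    """A promoter-DM, differentially expressed lncRNA with a significant
    methylation-expression correlation."""

    lnc_id: str
    subtype: str
    r_me: float
    p_me: float
    beta_diff: float
    log2fc: float
    concordant: bool


def epigenetically_altered(
    promoter_dmrs,
    de_results: pd.DataFrame,
    beta: pd.DataFrame,
    fpkm: pd.DataFrame,
    subtype: str = "",
    p_max: float = P_MAX_DEFAULT,
) -> list:
    """Classify epigenetically altered lncRNAs for one subtype.

    ``promoter_dmrs`` are DMRegions annotated as promoter-TSS of a lncRNA
    (classified hyper/hypo); ``de_results`` is the called DE table for the
    same subtype. For each lncRNA in the intersection, the per-sample
    promoter signal is the mean beta over the region's probes,
    log2-transformed after epsilon-clamping, correlated against
    log2(FPKM + 1). Records with p_me <= p_max are retained.
    """
    de_by_gene = de_results.set_index("gene_id")
    out = []
    for r in promoter_dmrs:
        if r.gene_id is None or r.category != "promoter-TSS":
            continue
        lid = r.gene_id
        if lid not in de_by_gene.index or lid not in fpkm.index:
            continue
        probes = [p for p in r.probe_ids if p in beta.index]
        if not probes:
            warnings.warn(f"promoter region of {lid} has no probes in beta matrix; skipped")
            continue
        mbeta = beta.loc[probes].mean(axis=0)
        msig = np.log2(np.maximum(mbeta.to_numpy(), BETA_EPS))
        expr = np.log2(fpkm.loc[lid, mbeta.index].to_numpy() + 1.0)
        r_me, p_me = pearson_with_p(msig, expr)
        if np.isnan(r_me) or p_me > p_max:
            continue
        log2fc = float(de_by_gene.loc[lid, "log2fc"])
        concordant = (r.direction == "hypo" and log2fc > 0) or (
            r.direction == "hyper" and log2fc < 0
        )
        out.append(EpiAlteredRecord(
            lnc_id=lid, subtype=subtype, r_me=r_me, p_me=p_me,
            beta_diff=float(r.beta_diff), log2fc=log2fc, concordant=concordant,
        ))
    return out


def epi_altered_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"lnc_id": r.lnc_id, "subtype": r.subtype, "r": r.r_me, "p": r.p_me,
             "beta_diff": r.beta_diff, "log2fc": r.log2fc,
             "concordant": r.concordant}
            for r in records
        ],
        columns=["lnc_id", "subtype", "r", "p", "beta_diff", "log2fc", "concordant"],
    )


@dataclass
class ChromatinOverlap:
    lnc_id: str
    chrom: str
    start: int
    end: int
    state: str
    overlap_bp: int


def _overlaps(start: int, end: int, segments):
    """Overlaps (>= 1 bp) of [start, end] (1-based inclusive) with labeled
    segments on the same chromosome."""
    out = []
    for chrom, s1, e1, state in segments:
        lo, hi = max(start, s1), min(end, e1)
        if hi >= lo:
            out.append((state, hi - lo + 1))
    return out


def chromatin_enrichment(
    dm_lnc_regions: dict,
    segmentation,
    background_lncs: dict,
    states_of_interest=STATES_OF_INTEREST,
):
    """Fisher test for chromatin-state marking of DM lncRNAs.

    ``dm_lnc_regions`` maps lnc_id -> (chrom, start, end) of its DM region;
    ``background_lncs`` maps non-DM tested lncRNA ids to their gene spans.
    A lncRNA counts as marked if its interval overlaps >= 1 bp of a state
    of interest. Returns (overlap records, 2x2 table, two-sided Fisher p).
    """
    if not background_lncs:
        raise ValueError("empty background")
    states_of_interest = set(states_of_interest)
    by_chrom: dict = {}
    for seg in segmentation:
        by_chrom.setdefault(seg[0], []).append(seg)

    overlaps = []

    def marked(lid, interval):
        chrom, start, end = interval
        hit = False
        for state, bp in _overlaps(start, end, by_chrom.get(chrom, [])):
            if state in states_of_interest:
                overlaps.append(ChromatinOverlap(lid, chrom, start, end, state, bp))
                hit = True
        return hit

    dm_marked = sum(marked(lid, iv) for lid, iv in sorted(dm_lnc_regions.items()))
    n_overlap_dm = len(overlaps)
    bg_marked = 0
    for lid, iv in sorted(background_lncs.items()):
        n_before = len(overlaps)
        if marked(lid, iv):
            bg_marked += 1
        del overlaps[n_before:]  # background overlaps are not reported
    table = np.array([
        [dm_marked, len(dm_lnc_regions) - dm_marked],
        [bg_marked, len(background_lncs) - bg_marked],
    ])
    p = fisher_exact_two_sided(table)
    return overlaps[:n_overlap_dm], table, p
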