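"""Gene annotation data model, format readers, and genomic-position logic.

Coordinates are GTF-style 1-based inclusive internally; BED input
(0-based half-open) is converted on read. Gene models are gene-level:
transcripts and exons in a GTF are aggregated under their ``gene_id``.

Promoter windows are +/- 2 kb around the strand-aware transcription start
site (TSS); the transcription termination site (TTS) window is +/- 2 kb
around the opposite end. cis protein-coding partners of a lncRNA are the
same-chromosome genes whose TSS lies within 100 kb of the lncRNA TSS
(boundary inclusive); farther same-chromosome genes are trans partners.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

PROMOTER_HALFWIDTH = 2000
TTS_HALFWIDTH = 2000
CIS_WINDOW_BP = 100_000

_BIOTYPES = {"lncRNA", "protein_coding"}
# GENCODE lncRNA-class biotypes mapped onto the lncRNA label
_LNC_ALIASES = {
    "lncRNA",
    "lincRNA",
    "antisense",
    "processed_transcript",
    "sense_intronic",
    "sense_overlapping",
    "3prime_overlapping_ncrna",
    "3prime_overlapping_ncRNA",
}


@dataclass(frozen=True)
class GeneModel:
    """A gene-level genomic record.

    ``start <= end`` always; the TSS is ``start`` on the + strand and
    ``end`` on the - strand, the TES/TTS the opposite end. Exons are
    sorted, non-overlapping, and contained in ``[start, end]``.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple = ()
    biotype: str = "other"

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end or self.start < 1:
            raise ValueError(f"{self.gene_id}: invalid span [{self.start}, {self.end}]")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for i, (s, e) in enumerate(exons):
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s}, {e}) outside gene span")
            if i > 0 and s <= exons[i - 1][1]:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomicRegionLabel:
    """Label for a genomic position relative to a gene set.

    ``category`` is one of promoter-TSS, exon, intron, TTS, intergenic;
    ``gene_id`` is None iff the category is intergenic. ``distance_to_tss``
    is signed in transcription direction (positive downstream of the TSS).
    """

    category: str
    gene_id: str | None
    distance_to_tss: int | None = None

    def __post_init__(self):
        if (self.category == "intergenic") != (self.gene_id is None):
            raise ValueError("gene_id must be None exactly when intergenic")


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attributes(attr_field: str) -> dict:
    return dict(_ATTR_RE.findall(attr_field))


def _normalize_biotype(raw: str) -> str:
    if raw in _LNC_ALIASES:
        return "lncRNA"
    if raw == "protein_coding":
        return "protein_coding"
    return "other"


def read_gtf(path) -> list[GeneModel]:
    """Read a GTF2.2 file into gene-level models.

    Exons of all transcripts are aggregated (union of non-overlapping
    intervals) under their gene. Unknown biotypes map to ``other``.
    Malformed lines raise with the line number; a duplicate ``gene_id``
    with conflicting coordinates raises.
    """
    spans: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GTF line {lineno}") from exc
            a = _parse_attributes(attrs)
            gid = a.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}: missing gene_id at line {lineno}")
            biotype = _normalize_biotype(a.get("gene_type", a.get("gene_biotype", "")))
            rec = spans.setdefault(
                gid,
                {"chrom": chrom, "strand": strand, "start": None, "end": None,
                 "biotype": biotype, "exons": []},
            )
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise ValueError(
                    f"{path}: gene_id {gid} with conflicting coordinates (line {lineno})"
                )
            if feature == "gene":
                if rec["start"] is not None and (rec["start"], rec["end"]) != (start_i, end_i):
                    raise ValueError(
                        f"{path}: duplicate gene_id {gid} with conflicting coordinates"
                        f" (line {lineno})"
                    )
                rec["start"], rec["end"] = start_i, end_i
                if biotype != "other":
                    rec["biotype"] = biotype
            elif feature == "exon":
                rec["exons"].append((start_i, end_i))

    genes = []
    for gid, rec in spans.items():
        exons = _merge_intervals(rec["exons"])
        start = rec["start"] if rec["start"] is not None else (exons[0][0] if exons else None)
        end = rec["end"] if rec["end"] is not None else (exons[-1][1] if exons else None)
        if start is None:
            raise ValueError(f"{path}: gene {gid} has neither gene record nor exons")
        genes.append(
            GeneModel(gene_id=gid, chrom=rec["chrom"], strand=rec["strand"],
                      start=start, end=end, exons=tuple(exons), biotype=rec["biotype"])
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _merge_intervals(intervals):
    if not intervals:
        return []
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 0:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _signed_tss_distance(pos: int, gene: GeneModel) -> int:
    d = pos - gene.tss
    return d if gene.strand == "+" else -d


def classify_position(
    chrom: str,
    pos: int,
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
    tts_halfwidth: int = TTS_HALFWIDTH,
) -> GenomicRegionLabel:
    """Classify a genomic position against a gene collection.

    Precedence: promoter-TSS > exon > intron > TTS > intergenic. Ties
    across genes within the winning category are broken by the smallest
    absolute TSS distance, then lexicographic gene_id. Total: intergenic
    is the fallback.
    """
    if pos < 1:
        raise ValueError("pos must be >= 1")
    order = {"promoter-TSS": 0, "exon": 1, "intron": 2, "TTS": 3}
    best = None  # (rank, |dist|, gene_id, dist)
    for g in genes:
        if g.chrom != chrom:
            continue
        dist = _signed_tss_distance(pos, g)
        cat = None
        if abs(pos - g.tss) <= promoter_halfwidth:
            cat = "promoter-TSS"
        elif g.start <= pos <= g.end:
            cat = "exon" if any(s <= pos <= e for s, e in g.exons) else "intron"
        elif abs(pos - g.tes) <= tts_halfwidth:
            cat = "TTS"
        if cat is None:
            continue
        key = (order[cat], abs(dist), g.gene_id)
        if best is None or key < best[0]:
            best = (key, g.gene_id, dist)
    if best is None:
        return GenomicRegionLabel("intergenic", None, None)
    (rank, _, _), gid, dist = best
    cat = ["promoter-TSS", "exon", "intron", "TTS"][rank]
    return GenomicRegionLabel(cat, gid, dist)


def assign_neighbors(
    lnc: GeneModel,
    pc_genes: Iterable[GeneModel],
    window_bp: int = CIS_WINDOW_BP,
):
    """Partition same-chromosome protein-coding genes into cis and trans
    partners of a lncRNA.

    Distance is TSS-to-TSS. cis: distance <= window_bp (boundary
    inclusive); trans: distance > window_bp on the same chromosome.
    Other-chromosome genes belong to neither set. Returns two lists of
    ``(GeneModel, distance_bp)``.
    """
    cis, trans = [], []
    for pc in pc_genes:
        if pc.biotype != "protein_coding":
            raise ValueError(f"{pc.gene_id} is not protein_coding")
        if pc.chrom != lnc.chrom:
            continue
        d = abs(lnc.tss - pc.tss)
        (cis if d <= window_bp else trans).append((pc, d))
    return cis, trans


def read_bed(path) -> list[tuple]:
    """Read BED4/6 into (chrom, start, end, name) with 1-based inclusive
    coordinates (converted from BED's 0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            out.append((chrom, start0 + 1, end0, name))
    return out


def read_gmt(path) -> dict:
    """Read a GMT file into {set_name: (description, [members])}."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}")
            sets[parts[0]] = (parts[1], [m for m in parts[2:] if m])
    return sets


def read_probe_manifest(path) -> pd.DataFrame:
    """Read a probe manifest TSV (probe_id, chrom, pos; 1-based)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    df["pos"] = df["pos"].astype(int)
    return df
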