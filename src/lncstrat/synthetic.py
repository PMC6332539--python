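"""Synthetic BCP-ALL-like cohort generator with planted ground truth.

Emulates the statistical structure the analysis assumes: a cohort of ~45
patients, most with paired initial-diagnosis (ID) and relapse (REL)
samples, grouped into molecular subtypes; lncRNA expression lower on
average than protein-coding expression; negative-binomial counts with a
shared per-patient random effect (the blocking structure duplicate
correlation must recover); logit-normal methylation beta values with
planted group shifts over contiguous probe runs (DMRs); and lncRNAs whose
expression is a monotone function of their simulated promoter M-value
(epigenetic coupling).

Everything is laid out on a single synthetic chromosome ``chrS`` so that
cis/trans logic is explicit: each lncRNA locus carries one protein-coding
gene within 100 kb (a guaranteed cis partner) and all other loci are
spaced farther apart (guaranteed trans partners).

All randomness flows from the single integer seed in :class:`TruthSpec`
through named generators; there is no global RNG state.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lncstrat.annotation import GeneModel

CHROM = "chrS"
_STATES = ("Quiescent", "Enhancer", "Txn", "Insulator", "Heterochrom")


@dataclass(frozen=True)
class TruthSpec:
    """Declarative description of a synthetic cohort and its planted truth.

    Cohort-structure defaults mirror a relapsed-leukemia discovery cohort:
    45 patients, 37 of them with paired ID/REL samples, in subtype groups
    DUX4 (12), Ph-like (11), NH-HeH (9), LH (3) and Other (10). Gene
    numbers are scaled down from genome scale for tractability.

    Planted-truth fields:

    * ``planted_subtype_de`` — (gene_id, subtype, log2 effect): multiplicative
      expression shift for all samples of the subtype.
    * ``planted_relapse_de`` — (gene_id, subtype, log2 effect): shift at REL
      within the subtype.
    * ``planted_dmrs`` — (lnc_id, kind, subtype, beta_shift, n_probes):
      beta-scale methylation shift over the first ``n_probes`` probes of the
      lncRNA's ``promoter`` or ``body`` probe run, in the subtype's samples.
    * ``planted_epi_coupled`` — (lnc_id, sign, strength): expression log2 mean
      gains ``sign * strength * (M - mean(M))`` where M is the simulated
      per-sample promoter M-value; sign -1 is methylation-repressed.
    * ``planted_pathways`` — (set_name, member_pc_ids): gene sets emitted to
      the GMT whose membership is known truth.
    """

    n_patients: int = 45
    paired_fraction: float = 37 / 45
    subtype_labels: tuple = (
        ("DUX4", 12), ("Ph-like", 11), ("NH-HeH", 9), ("LH", 3), ("Other", 10),
    )
    n_lnc: int = 200
    n_pc: int = 400
    planted_subtype_de: tuple = ()
    planted_relapse_de: tuple = ()
    planted_dmrs: tuple = ()
    planted_epi_coupled: tuple = ()
    planted_baseline: tuple = ()
    planted_pathways: tuple = ()
    dispersion: float = 0.2
    beta_noise_sd: float = 0.5
    patient_sd: float = 0.3
    seed: int = 0
    # expression baselines (log2 scale); lncRNA mean below PC mean
    lnc_log2_mean: float = 3.0
    pc_log2_mean: float = 5.5
    baseline_sd: float = 1.2
    libsize_sd: float = 0.2
    # layout
    locus_span: int = 250_000
    n_random_sets: int = 8

    def __post_init__(self):
        if self.n_patients <= 0 or self.n_lnc <= 0 or self.n_pc <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ValueError("paired_fraction must be in [0, 1]")
        if self.dispersion < 0 or self.beta_noise_sd <= 0:
            raise ValueError("dispersion must be >= 0 and beta_noise_sd > 0")
        total = sum(c for _, c in self.subtype_labels)
        if total != self.n_patients:
            raise ValueError(
                f"subtype counts sum to {total}, expected n_patients={self.n_patients}"
            )
        object.__setattr__(
            self, "subtype_labels", tuple((str(s), int(c)) for s, c in self.subtype_labels)
        )
        object.__setattr__(self, "planted_subtype_de",
                           tuple((str(g), str(s), float(e)) for g, s, e in self.planted_subtype_de))
        object.__setattr__(self, "planted_relapse_de",
                           tuple((str(g), str(s), float(e)) for g, s, e in self.planted_relapse_de))
        object.__setattr__(self, "planted_dmrs",
                           tuple((str(g), str(k), str(s), float(d), int(n))
                                 for g, k, s, d, n in self.planted_dmrs))
        object.__setattr__(self, "planted_epi_coupled",
                           tuple((str(g), int(sg), float(st))
                                 for g, sg, st in self.planted_epi_coupled))
        object.__setattr__(self, "planted_baseline",
                           tuple((str(g), float(o)) for g, o in self.planted_baseline))
        object.__setattr__(self, "planted_pathways",
                           tuple((str(n), tuple(str(m) for m in ms))
                                 for n, ms in self.planted_pathways))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthSpec":
        d = json.loads(text)
        return cls(**d)


def lnc_id(i: int) -> str:
    return f"LNC{i + 1:04d}"


def pc_id(i: int) -> str:
    return f"PC{i + 1:04d}"


@dataclass
class Annotation:
    """Synthetic annotation bundle produced by :func:`make_annotation`."""

    genes: list
    probes: pd.DataFrame  # probe_id, chrom, pos
    probe_regions: dict   # (gene_id, kind) -> list of probe ids
    chrom_states: list    # (chrom, start1, end1, state), 1-based inclusive
    gene_sets: dict       # name -> list of member ids
    chrom_length: int
    gene_lengths: pd.Series  # exonic length per gene_id

    @property
    def genes_by_id(self) -> dict:
        return {g.gene_id: g for g in self.genes}

    @property
    def lnc_ids(self) -> list:
        return [g.gene_id for g in self.genes if g.biotype == "lncRNA"]

    @property
    def pc_ids(self) -> list:
        return [g.gene_id for g in self.genes if g.biotype == "protein_coding"]


def _make_gene(rng, gid, biotype, start, length, strand):
    end = start + length - 1
    n_ex = int(rng.integers(1, 4))
    if n_ex == 1:
        exons = ((start, end),)
    else:
        # cut the span into n_ex exons separated by fixed-size introns
        intron = max(200, length // (4 * n_ex))
        usable = length - intron * (n_ex - 1)
        sizes = np.full(n_ex, usable // n_ex)
        sizes[-1] += usable - sizes.sum()
        exons = []
        pos = start
        for sz in sizes:
            exons.append((pos, pos + int(sz) - 1))
            pos += int(sz) + intron
        exons = tuple(exons)
        end = exons[-1][1]
    return GeneModel(gene_id=gid, chrom=CHROM, strand=strand, start=start,
                     end=end, exons=exons, biotype=biotype)


def make_annotation(spec: TruthSpec) -> Annotation:
    """Lay out genes, probes, chromatin states and gene sets on ``chrS``.

    Guarantees: every lncRNA has >= 1 protein-coding gene with TSS distance
    <= 100 kb (its locus partner) and, provided there are >= 2 loci, >= 1
    farther than 100 kb on the same chromosome. Probes tile lncRNA
    promoters (+/- 2 kb of the TSS, spacing 350 bp), gene bodies and
    intergenic space. The chromatin segmentation covers the chromosome in
    10 kb bins over five states including Enhancer and Insulator.
    """
    if spec.n_pc < spec.n_lnc:
        raise ValueError(
            f"layout infeasible: need n_pc >= n_lnc to give every lncRNA a cis "
            f"partner (got n_pc={spec.n_pc}, n_lnc={spec.n_lnc})"
        )
    if spec.locus_span < 210_000:
        raise ValueError(
            f"layout infeasible: locus_span={spec.locus_span} cannot hold a "
            "gene pair within 100 kb while keeping other loci trans (> 100 kb)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    margin = 50_000
    n_loci = spec.n_pc  # one locus per lncRNA (with paired PC) + lone-PC loci
    genes = []
    probe_rows = []
    probe_regions: dict = {}

    def add_probes(gid, kind, positions):
        ids = []
        for p in positions:
            pid = f"cg{len(probe_rows) + 1:06d}"
            probe_rows.append((pid, CHROM, int(p)))
            ids.append(pid)
        probe_regions[(gid, kind)] = ids

    for i in range(spec.n_lnc):
        base = margin + i * spec.locus_span
        length = int(rng.integers(8000, 12001))
        strand = "+" if rng.random() < 0.5 else "-"
        g = _make_gene(rng, lnc_id(i), "lncRNA", base + 2_500, length, strand)
        genes.append(g)
        # promoter probes: one 6-probe cluster around the TSS, gaps 350 bp
        add_probes(g.gene_id, "promoter", [g.tss + o for o in (-875, -525, -175, 175, 525, 875)])
        # body probes: 4-probe cluster at the gene midpoint (> 2 kb from both ends)
        mid = (g.start + g.end) // 2
        add_probes(g.gene_id, "body", [mid + o for o in (-600, -200, 200, 600)])
        # intergenic probes: isolated singletons far from any gene
        add_probes(g.gene_id, "intergenic",
                   [base + spec.locus_span - 60_000, base + spec.locus_span - 55_000])
        # paired cis protein-coding gene 30-60 kb downstream of the lncRNA TSS
        offset = int(rng.integers(30_000, 60_001))
        pc_strand = "+" if rng.random() < 0.5 else "-"
        pc_tss = g.tss + offset
        pc_len = int(rng.integers(5000, 15001))
        pc_start = pc_tss if pc_strand == "+" else pc_tss - pc_len + 1
        genes.append(_make_gene(rng, pc_id(i), "protein_coding", pc_start, pc_len, pc_strand))

    for j in range(spec.n_lnc, spec.n_pc):
        base = margin + j * spec.locus_span
        pc_len = int(rng.integers(5000, 15001))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(_make_gene(rng, pc_id(j), "protein_coding", base + 2_500, pc_len, strand))

    chrom_length = 2 * margin + n_loci * spec.locus_span
    # chromatin segmentation: contiguous 10 kb bins, random state per bin
    bin_size = 10_000
    n_bins = int(np.ceil(chrom_length / bin_size))
    states = rng.choice(len(_STATES), size=n_bins)
    chrom_states = []
    for b in range(n_bins):
        s1 = b * bin_size + 1
        e1 = min((b + 1) * bin_size, chrom_length)
        chrom_states.append((CHROM, s1, e1, _STATES[states[b]]))

    pc_all = [pc_id(i) for i in range(spec.n_pc)]
    gene_sets = {}
    for name, members in spec.planted_pathways:
        missing = [m for m in members if m not in pc_all]
        if missing:
            raise ValueError(f"planted pathway {name}: unknown member {missing[0]}")
        gene_sets[name] = list(members)
    for k in range(spec.n_random_sets):
        size = int(rng.integers(8, min(21, spec.n_pc + 1)))
        members = sorted(rng.choice(pc_all, size=size, replace=False).tolist())
        gene_sets[f"RANDSET{k + 1:02d}"] = members

    probes = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos"])
    lengths = pd.Series(
        {g.gene_id: sum(e - s + 1 for s, e in g.exons) for g in genes}, name="length"
    )
    return Annotation(genes=genes, probes=probes, probe_regions=probe_regions,
                      chrom_states=chrom_states, gene_sets=gene_sets,
                      chrom_length=chrom_length, gene_lengths=lengths)


@dataclass
class Cohort:
    """Simulated cohort bundle produced by :func:`simulate_cohort`."""

    counts: pd.DataFrame   # genes x samples, integer
    fpkm: pd.DataFrame     # genes x samples
    beta: pd.DataFrame     # probes x samples, in (0, 1)
    samples: pd.DataFrame  # sample_id, patient_id, timepoint, subtype
    truth: dict
    gene_lengths: pd.Series
    library_sizes: pd.Series


def _build_samples(spec: TruthSpec) -> pd.DataFrame:
    rows = []
    pidx = 0
    for subtype, count in spec.subtype_labels:
        n_paired = int(round(spec.paired_fraction * count))
        for k in range(count):
            pidx += 1
            patient = f"P{pidx:04d}"
            if k < n_paired:
                rows.append((f"{patient}_ID", patient, "ID", subtype))
                rows.append((f"{patient}_REL", patient, "REL", subtype))
            else:
                tp = "ID" if (k - n_paired) % 2 == 0 else "REL"
                rows.append((f"{patient}_{tp}", patient, tp, subtype))
    return pd.DataFrame(rows, columns=["sample_id", "patient_id", "timepoint", "subtype"])


def fpkm_from_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM = counts / (exonic length in kb x library size in millions);
    library size is the column sum of counts."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValueError(f"zero library size for sample {bad}")
    len_kb = lengths.loc[counts.index].astype(float) / 1000.0
    return counts.div(len_kb, axis=0).div(lib / 1e6, axis=1)


def simulate_cohort(spec: TruthSpec, annotation: Annotation) -> Cohort:
    """Draw the count, FPKM and beta matrices plus sample metadata.

    Methylation is drawn first (logit-normal per probe with planted group
    shifts over DMR probe runs); expression then conditions on the realized
    promoter M-values of epigenetically coupled lncRNAs.
    """
    gene_ids = [g.gene_id for g in annotation.genes]
    gene_set = set(gene_ids)
    for g, _s, _e in spec.planted_subtype_de + spec.planted_relapse_de:
        if g not in gene_set:
            raise ValueError(f"planted id {g} missing from annotation")
    for g, kind, _s, _d, n in spec.planted_dmrs:
        key = (g, kind)
        if key not in annotation.probe_regions:
            raise ValueError(f"planted DMR id {g} ({kind}) missing from annotation")
        if n > len(annotation.probe_regions[key]):
            raise ValueError(
                f"planted DMR {g}: requested {n} probes, region has "
                f"{len(annotation.probe_regions[key])}"
            )
    for g, _sg, _st in spec.planted_epi_coupled:
        if (g, "promoter") not in annotation.probe_regions:
            raise ValueError(f"planted epi-coupled id {g} missing from annotation")
    for g, _o in spec.planted_baseline:
        if g not in gene_set:
            raise ValueError(f"planted id {g} missing from annotation")

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2]))
    samples = _build_samples(spec)
    sample_ids = samples["sample_id"].tolist()
    n_s = len(sample_ids)
    subtype_of = samples.set_index("sample_id")["subtype"]
    tp_of = samples.set_index("sample_id")["timepoint"]

    # --- methylation ---
    probes = annotation.probes
    n_p = len(probes)
    b0 = rng.uniform(0.3, 0.7, size=n_p)
    mu_logit = np.log2(b0 / (1.0 - b0))[:, None] * np.ones((1, n_s))
    probe_idx = {pid: i for i, pid in enumerate(probes["probe_id"])}
    planted_dmr_probes = {}
    for g, kind, subtype, shift, n in spec.planted_dmrs:
        pids = annotation.probe_regions[(g, kind)][:n]
        planted_dmr_probes[f"{g}:{kind}:{subtype}"] = pids
        rows = [probe_idx[p] for p in pids]
        cols = np.flatnonzero((subtype_of[sample_ids] == subtype).to_numpy())
        target = np.clip(b0[rows] + shift, 0.02, 0.98)
        mu_logit[np.ix_(rows, cols)] = np.log2(target / (1.0 - target))[:, None]
    logit = mu_logit + rng.normal(0.0, spec.beta_noise_sd, size=(n_p, n_s))
    beta = 1.0 / (1.0 + np.exp2(-logit))
    beta_df = pd.DataFrame(beta, index=probes["probe_id"].tolist(), columns=sample_ids)

    # promoter M-values for coupled lncRNAs (mean beta over promoter probes)
    eps = 1e-3
    coupling = np.zeros((len(gene_ids), n_s))
    gindex = {g: i for i, g in enumerate(gene_ids)}
    for g, sign, strength in spec.planted_epi_coupled:
        pids = annotation.probe_regions[(g, "promoter")]
        mb = beta_df.loc[pids].mean(axis=0).to_numpy()
        mb = np.clip(mb, eps, 1.0 - eps)
        M = np.log2(mb / (1.0 - mb))
        coupling[gindex[g], :] = sign * strength * (M - M.mean())

    # --- expression ---
    is_lnc = np.array([g.biotype == "lncRNA" for g in annotation.genes])
    base = np.where(
        is_lnc,
        rng.normal(spec.lnc_log2_mean, spec.baseline_sd, size=len(gene_ids)),
        rng.normal(spec.pc_log2_mean, spec.baseline_sd, size=len(gene_ids)),
    )
    for g, off in spec.planted_baseline:
        base[gindex[g]] += off
    log2mu = base[:, None] + coupling
    for g, subtype, eff in spec.planted_subtype_de:
        cols = np.flatnonzero((subtype_of[sample_ids] == subtype).to_numpy())
        log2mu[gindex[g], cols] += eff
    for g, subtype, eff in spec.planted_relapse_de:
        cols = np.flatnonzero(
            ((subtype_of[sample_ids] == subtype) & (tp_of[sample_ids] == "REL")).to_numpy()
        )
        log2mu[gindex[g], cols] += eff
    # patient random effect: gene-specific profile shared by the patient's
    # ID and REL samples (a global per-sample factor would cancel in CPM
    # normalization and leave nothing for duplicate correlation to recover)
    patients = samples["patient_id"].unique()
    pat_index = {p: i for i, p in enumerate(patients)}
    pe = rng.normal(0.0, spec.patient_sd, size=(len(gene_ids), len(patients)))
    log2mu += pe[:, [pat_index[p] for p in samples["patient_id"]]]
    sf = np.exp2(rng.normal(0.0, spec.libsize_sd, size=n_s))
    mu = np.exp2(log2mu) * sf[None, :]
    if spec.dispersion > 0:
        lam = rng.gamma(shape=1.0 / spec.dispersion, scale=mu * spec.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    fpkm_df = fpkm_from_counts(counts_df, annotation.gene_lengths)

    truth = {
        "spec": json.loads(spec.to_json()),
        "samples": samples.to_dict(orient="records"),
        "planted_subtype_de": [list(t) for t in spec.planted_subtype_de],
        "planted_relapse_de": [list(t) for t in spec.planted_relapse_de],
        "planted_dmrs": [list(t) for t in spec.planted_dmrs],
        "planted_dmr_probes": planted_dmr_probes,
        "planted_epi_coupled": [list(t) for t in spec.planted_epi_coupled],
        "planted_pathways": [[n, list(m)] for n, m in spec.planted_pathways],
    }
    return Cohort(counts=counts_df, fpkm=fpkm_df, beta=beta_df, samples=samples,
                  truth=truth, gene_lengths=annotation.gene_lengths,
                  library_sizes=counts_df.sum(axis=0))


# ---------------------------------------------------------------- writers

def write_annotation(annotation: Annotation, outdir) -> None:
    """Write annotation.gtf, probes.tsv, chromhmm.bed and genesets.gmt."""
    import os

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "annotation.gtf"), "w") as fh:
        for g in annotation.genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
            fh.write(f"{g.chrom}\tlncstrat\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tlncstrat\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
    annotation.probes.to_csv(os.path.join(outdir, "probes.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "chromhmm.bed"), "w") as fh:
        for chrom, s1, e1, state in annotation.chrom_states:
            fh.write(f"{chrom}\t{s1 - 1}\t{e1}\t{state}\n")
    with open(os.path.join(outdir, "genesets.gmt"), "w") as fh:
        for name, members in annotation.gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
    annotation.gene_lengths.rename_axis("gene_id").reset_index().to_csv(
        os.path.join(outdir, "gene_lengths.tsv"), sep="\t", index=False
    )


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write counts.tsv, fpkm.tsv, beta.tsv, samples.tsv and truth.json."""
    import os

    os.makedirs(outdir, exist_ok=True)
    cohort.counts.rename_axis("gene_id").to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
    cohort.fpkm.rename_axis("gene_id").to_csv(
        os.path.join(outdir, "fpkm.tsv"), sep="\t", float_format="%.10g"
    )
    cohort.beta.rename_axis("probe_id").to_csv(
        os.path.join(outdir, "beta.tsv"), sep="\t", float_format="%.10g"
    )
    cohort.samples.to_csv(os.path.join(outdir, "samples.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(cohort.truth, fh, indent=1)


def read_matrix(path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = feature id)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")
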