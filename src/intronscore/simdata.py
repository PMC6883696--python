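"""Synthetic genomes, variants, tracks and reporter counts with planted truth.

The generator emulates the structure of the real inputs at toy scale: a
single contig carrying multi-exon genes on both strands whose introns all
start GT and end AG inside consensus-rich splice windows; pathogenic
variants planted to disrupt donor/acceptor consensus (on-ss) or planted
RBP motifs (off-ss) near structured, conserved exons; neutral variants
placed uniformly with population allele frequencies; per-residue protein
tracks, domain/PTM tables and a per-base conservation track; and
negative-binomial reporter count tables drawn from the interaction model
with replicate random intercepts.

Every output file has its own RNG stream derived from the master seed, so
regenerating any single artifact with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .rbp import ALPHABET, RbpPwm, write_pwms

_BASES = np.array(list(ALPHABET))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# consensus profiles (offset -> (base, probability)); GT / AG are invariant
DONOR_PROFILE = {-3: ("A", 0.6), -2: ("A", 0.7), -1: ("G", 0.8),
                 1: ("G", 1.0), 2: ("T", 1.0), 3: ("A", 0.6), 4: ("A", 0.7),
                 5: ("G", 0.8), 6: ("T", 0.55), 7: ("T", 0.4)}
ACCEPTOR_PROFILE = {**{o: ("Y", 0.9) for o in range(-13, -3)},
                    -3: ("C", 0.65), -2: ("A", 1.0), -1: ("G", 1.0),
                    1: ("G", 0.55)}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic bundle.

    Defaults are sized so a full train/evaluate round with all features
    runs in minutes on one CPU while keeping the planted effects at
    realistic strengths (strong conservation contrast at pathogenic loci,
    canonical-site disruption, moderate reporter effect sizes).
    """

    seed: int = 0
    chrom: str = "chr1"
    n_genes: int = 80
    exons_per_gene: int = 5
    exon_length: int = 90          # divisible by 3: every exon is coding
    intron_length: int = 140
    spacer_length: int = 200
    # RBP motifs
    n_rbp_motifs: int = 8
    rbp_motif_lengths: tuple[int, ...] = (5, 6, 7)
    rbp_consensus_prob: float = 0.85
    rbp_n_sites: float = 100.0
    # variants
    n_pathogenic: int = 1000
    n_neutral: int = 1000
    pathogenic_on_ss_fraction: float = 0.5
    rbp_disruption_prob: float = 0.7   # off-ss pathogenic: motif planted
    offss_distance_scale: float = 25.0  # exponential decay of distances
    maf_fail_fraction: float = 0.25    # neutrals failing the 10% MAF filter
    # conservation
    cons_background_mean: float = 0.0
    cons_background_sd: float = 0.7
    cons_pathogenic_mean: float = 2.5
    cons_pathogenic_sd: float = 0.5
    cons_halo_bp: int = 7
    # reporter assay
    assetseq_n_isnv: int = 30
    assetseq_null_fraction: float = 0.5
    assetseq_replicates: int = 5
    assetseq_mean_depth: float = 100.0
    assetseq_aberrant_log_ratio: float = -1.0
    assetseq_dispersion: float = 0.1
    assetseq_beta3: float = 1.0
    assetseq_random_intercept_sd: float = 0.3

    def __post_init__(self) -> None:
        if min(self.n_genes, self.exons_per_gene, self.exon_length,
               self.intron_length, self.n_pathogenic, self.n_neutral) < 1:
            raise ValueError("all counts must be positive")
        for p in (self.pathogenic_on_ss_fraction, self.rbp_disruption_prob,
                  self.maf_fail_fraction, self.assetseq_null_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.exon_length % 3:
            raise ValueError("exon_length must be a codon multiple")
        if self.intron_length < 40:
            raise ValueError("introns must fit both splice windows")

    def rng(self, stream: str) -> np.random.Generator:
        """Named RNG stream derived from the master seed (stable across
        processes, unlike the builtin string hash)."""
        import zlib

        digest = zlib.crc32(stream.encode()) % (2**31)
        return np.random.default_rng([self.seed, digest])


@dataclass
class _Gene:
    name: str
    strand: str
    start: int                       # genomic start (0-based) of the gene
    transcript_seq: list[str]        # mutable during planning
    exon_bounds_t: list[tuple[int, int]]   # transcript coords, half-open
    intron_bounds_t: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return len(self.transcript_seq)

    def genomic_pos(self, t: int) -> int:
        """Genomic 0-based coordinate of transcript coordinate t."""
        if self.strand == "+":
            return self.start + t
        return self.start + self.length - 1 - t

    def genomic_base(self, t: int) -> str:
        b = self.transcript_seq[t]
        return b if self.strand == "+" else _COMP[b]

    def exon_intervals_genomic(self) -> list[tuple[int, int]]:
        out = []
        for (a, b) in self.exon_bounds_t:
            if self.strand == "+":
                out.append((self.start + a, self.start + b))
            else:
                out.append((self.start + self.length - b,
                            self.start + self.length - a))
        return sorted(out)


@dataclass
class SimPlan:
    """Everything derived deterministically from a SimConfig."""

    config: SimConfig
    genes: list[_Gene]
    chrom_length: int
    rbp_pwms: list[RbpPwm]
    variants: pd.DataFrame           # id, pos (1-based), ref, alt, label, ...
    important_exons: set[tuple[str, int]]  # (transcript, exon transcript idx)


def _sample_base(rng, base: str, prob: float) -> str:
    if base == "Y":  # pyrimidine
        if rng.random() < prob:
            return "C" if rng.random() < 0.5 else "T"
        return str(rng.choice(_BASES))
    if rng.random() < prob:
        return base
    return str(rng.choice([b for b in ALPHABET if b != base]))


def _make_genes(cfg: SimConfig, rng) -> tuple[list[_Gene], int]:
    genes = []
    cursor = cfg.spacer_length
    for g in range(cfg.n_genes):
        strand = "+" if g % 2 == 0 else "-"
        seq: list[str] = []
        exon_bounds, intron_bounds = [], []
        for e in range(cfg.exons_per_gene):
            estart = len(seq)
            seq.extend(rng.choice(_BASES, size=cfg.exon_length))
            exon_bounds.append((estart, len(seq)))
            if e < cfg.exons_per_gene - 1:
                istart = len(seq)
                seq.extend(rng.choice(_BASES, size=cfg.intron_length))
                intron_bounds.append((istart, len(seq)))
        # stamp consensus splice windows (acceptor +1 is exonic, so stamping
        # happens once every exon exists)
        for (istart, iend) in intron_bounds:
            for off, (base, p) in DONOR_PROFILE.items():
                t = istart + off if off < 0 else istart + off - 1
                seq[t] = _sample_base(rng, base, p)
            for off, (base, p) in ACCEPTOR_PROFILE.items():
                t = iend + off if off < 0 else iend + off - 1
                seq[t] = _sample_base(rng, base, p)
        genes.append(_Gene(f"gene{g:03d}", strand, cursor, list(map(str, seq)),
                           exon_bounds, intron_bounds))
        cursor += len(seq) + cfg.spacer_length
    return genes, cursor


def _make_rbp_pwms(cfg: SimConfig, rng) -> list[RbpPwm]:
    pwms = []
    for i in range(cfg.n_rbp_motifs):
        k = int(rng.choice(cfg.rbp_motif_lengths))
        counts = np.zeros((k, 4))
        for pos in range(k):
            cons = rng.integers(4)
            counts[pos] = cfg.rbp_n_sites * (1 - cfg.rbp_consensus_prob) / 3
            counts[pos, cons] = cfg.rbp_n_sites * cfg.rbp_consensus_prob
        pwms.append(RbpPwm(f"RBP{i:02d}", counts, cfg.rbp_n_sites))
    return pwms


def _plan_variants(cfg: SimConfig, genes: list[_Gene], pwms: list[RbpPwm],
                   rng) -> tuple[pd.DataFrame, set[tuple[str, int]]]:
    """Choose variant loci, plant off-ss motifs, record the truth table."""
    used: set[int] = set()
    # common variants are depleted from conserved elements, so neutral
    # placement avoids the conserved halo planted around pathogenic loci
    conserved_halo: set[int] = set()
    important: set[tuple[str, int]] = set()
    rows = []
    il = cfg.intron_length
    on_ss_offsets = ([("donor", d) for d in range(1, 8)]
                     + [("acceptor", a) for a in range(-13, 0)])

    def pick_intron():
        gene = genes[rng.integers(len(genes))]
        idx = int(rng.integers(len(gene.intron_bounds_t)))
        return gene, idx

    def register(gene, t, alt_t, label, mechanism, maf, d_donor):
        gpos = gene.genomic_pos(t)
        if gpos in used:
            return False
        if label == "neutral" and gpos in conserved_halo:
            return False
        used.add(gpos)
        if label == "pathogenic":
            conserved_halo.update(range(gpos - cfg.cons_halo_bp,
                                        gpos + cfg.cons_halo_bp + 1))
        ref = gene.genomic_base(t)
        alt = alt_t if gene.strand == "+" else _COMP[alt_t]
        rows.append({"pos": gpos + 1, "ref": ref, "alt": alt, "label": label,
                     "mechanism": mechanism, "maf": maf,
                     "transcript": gene.name, "donor_distance": d_donor})
        return True

    n_path_on = int(round(cfg.n_pathogenic * cfg.pathogenic_on_ss_fraction))
    n_path_off = cfg.n_pathogenic - n_path_on

    placed = 0
    while placed < n_path_on:
        gene, ii = pick_intron()
        istart, iend = gene.intron_bounds_t[ii]
        side, off = on_ss_offsets[rng.integers(len(on_ss_offsets))]
        t = istart + off - 1 if side == "donor" else iend + off
        ref_t = gene.transcript_seq[t]
        alt_t = str(rng.choice([b for b in ALPHABET if b != ref_t]))
        if register(gene, t, alt_t, "pathogenic", f"splice_{side}", np.nan,
                    t - istart + 1):
            nearest = ii if (t - istart + 1) <= (iend - t) else ii + 1
            important.add((gene.name, nearest))
            placed += 1

    placed = 0
    while placed < n_path_off:
        gene, ii = pick_intron()
        istart, iend = gene.intron_bounds_t[ii]
        d = 8 + int(rng.exponential(cfg.offss_distance_scale))
        d = min(d, il - 14 - 1)
        t = istart + d - 1
        if rng.random() < cfg.rbp_disruption_prob:
            pwm = pwms[rng.integers(len(pwms))]
            cons = pwm.consensus()
            center = pwm.k // 2
            start = t - center
            if start < istart + 7 or start + pwm.k > iend - 13:
                continue
            if any(gene.genomic_pos(tt) in used for tt in range(start, start + pwm.k)):
                continue
            for j, b in enumerate(cons):
                gene.transcript_seq[start + j] = b
            worst = ALPHABET[int(np.argmin(pwm.counts[center]))]
            if worst == cons[center]:
                worst = ALPHABET[int(np.argsort(pwm.counts[center])[0])]
            mech = f"rbp_{pwm.name}"
            alt_t = worst
        else:
            mech = "conservation_only"
            ref_t = gene.transcript_seq[t]
            alt_t = str(rng.choice([b for b in ALPHABET if b != ref_t]))
        if register(gene, t, alt_t, "pathogenic", mech, np.nan, d):
            nearest = ii if d <= (iend - t) else ii + 1
            important.add((gene.name, nearest))
            placed += 1

    placed = 0
    while placed < cfg.n_neutral:
        gene, ii = pick_intron()
        istart, iend = gene.intron_bounds_t[ii]
        t = int(rng.integers(istart, iend))
        ref_t = gene.transcript_seq[t]
        alt_t = str(rng.choice([b for b in ALPHABET if b != ref_t]))
        if rng.random() < cfg.maf_fail_fraction:
            maf = float(rng.uniform(0.005, 0.10))
        else:
            maf = float(rng.uniform(0.101, 0.5))
        if register(gene, t, alt_t, "neutral", "none", maf, t - istart + 1):
            placed += 1

    df = pd.DataFrame(rows).sort_values("pos").reset_index(drop=True)
    df.insert(0, "variant_id", [f"isnv{i:05d}" for i in range(len(df))])
    return df, important


@lru_cache(maxsize=4)
def _cached_plan(cfg: SimConfig) -> SimPlan:
    rng = cfg.rng("plan")
    genes, chrom_length = _make_genes(cfg, rng)
    pwms = _make_rbp_pwms(cfg, cfg.rng("rbp"))
    variants, important = _plan_variants(cfg, genes, pwms, cfg.rng("variants"))
    return SimPlan(cfg, genes, chrom_length, pwms, variants, important)


def build_plan(cfg: SimConfig) -> SimPlan:
    return _cached_plan(cfg)


def clear_plan_cache() -> None:
    """Drop memoised plans (used to prove regeneration is deterministic)."""
    _cached_plan.cache_clear()


def _chromosome_sequence(plan: SimPlan) -> str:
    cfg = plan.config
    rng = cfg.rng("spacers")
    seq = rng.choice(_BASES, size=plan.chrom_length)
    for gene in plan.genes:
        ts = "".join(gene.transcript_seq)
        if gene.strand == "-":
            ts = "".join(_COMP[b] for b in reversed(ts))
        seq[gene.start:gene.start + gene.length] = list(ts)
    return "".join(seq)


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def make_reference_bundle(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Write genome FASTA (+ index), GTF gene models and RBP motif file."""
    import pyfaidx

    plan = build_plan(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "genome.fa"
    seq = _chromosome_sequence(plan)
    with open(fasta, "w") as fh:
        fh.write(f">{cfg.chrom}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    pyfaidx.Faidx(str(fasta))
    gtf = out / "genes.gtf"
    with open(gtf, "w") as fh:
        for gene in plan.genes:
            frame = 0
            for (a, b) in gene.exon_intervals_genomic():
                attrs = (f'gene_id "{gene.name}"; '
                         f'transcript_id "{gene.name}.t1";')
                for feat in ("exon", "CDS"):
                    fh.write("\t".join([cfg.chrom, "sim", feat, str(a + 1),
                                        str(b), ".", gene.strand,
                                        str(frame) if feat == "CDS" else ".",
                                        attrs]) + "\n")
    motifs = out / "rbp_motifs.tsv"
    write_pwms(plan.rbp_pwms, motifs)
    return {"fasta": fasta, "gtf": gtf, "rbp_motifs": motifs}


def make_variant_sets(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Write the VCF and the truth-label sidecar TSV."""
    plan = build_plan(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    vcf = out / "variants.vcf"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={cfg.chrom},length={plan.chrom_length}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description='
                 '"Allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in plan.variants.itertuples():
            info = f"AF={row.maf:.4f}" if np.isfinite(row.maf) else "."
            fh.write(f"{cfg.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t"
                     f"{row.alt}\t.\tPASS\t{info}\n")
    labels = out / "labels.tsv"
    plan.variants.to_csv(labels, sep="\t", index=False)
    return {"vcf": vcf, "labels": labels}


def make_auxiliary_tracks(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Write residue tracks, domain/PTM tables and the conservation bedGraph."""
    plan = build_plan(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    rng = cfg.rng("protein")
    track_rows, domain_rows, ptm_rows = [], [], []
    res_per_exon = cfg.exon_length // 3
    for gene in plan.genes:
        tid = f"{gene.name}.t1"
        n_res = cfg.exons_per_gene * res_per_exon
        disorder = rng.uniform(0.4, 0.9, size=n_res)
        asa = rng.uniform(60.0, 120.0, size=n_res)
        ss = rng.choice(list("CCCHE"), size=n_res)
        for e in range(cfg.exons_per_gene):
            if (gene.name, e) in plan.important_exons:
                sl = slice(e * res_per_exon, (e + 1) * res_per_exon)
                disorder[sl] = rng.uniform(0.0, 0.3, size=res_per_exon)
                asa[sl] = rng.uniform(10.0, 50.0, size=res_per_exon)
                ss[sl] = rng.choice(list("HHHE"), size=res_per_exon)
                domain_rows.append({"protein_id": tid,
                                    "start": e * res_per_exon + 1,
                                    "end": (e + 1) * res_per_exon,
                                    "name": f"DOM_{gene.name}_{e}"})
                for p in rng.choice(np.arange(e * res_per_exon + 1,
                                              (e + 1) * res_per_exon + 1),
                                    size=2, replace=False):
                    ptm_rows.append({"protein_id": tid, "position": int(p),
                                     "type": "phospho"})
        for i in range(n_res):
            track_rows.append({"protein_id": tid, "residue": i + 1,
                               "disorder": round(float(disorder[i]), 4),
                               "ss": str(ss[i]),
                               "asa": round(float(asa[i]), 2)})
    tracks = out / "residue_tracks.tsv"
    pd.DataFrame(track_rows).to_csv(tracks, sep="\t", index=False)
    domains = out / "domains.tsv"
    pd.DataFrame(domain_rows,
                 columns=["protein_id", "start", "end", "name"]
                 ).to_csv(domains, sep="\t", index=False)
    ptms = out / "ptms.tsv"
    pd.DataFrame(ptm_rows, columns=["protein_id", "position", "type"]
                 ).to_csv(ptms, sep="\t", index=False)

    rng = cfg.rng("conservation")
    values = rng.normal(cfg.cons_background_mean, cfg.cons_background_sd,
                        size=plan.chrom_length)
    halo = cfg.cons_halo_bp
    for row in plan.variants.itertuples():
        if row.label != "pathogenic":
            continue
        p0 = row.pos - 1
        lo, hi = max(p0 - halo, 0), min(p0 + halo + 1, plan.chrom_length)
        values[lo:hi] = rng.normal(cfg.cons_pathogenic_mean,
                                   cfg.cons_pathogenic_sd, size=hi - lo)
    bedgraph = out / "conservation.bedGraph"
    with open(bedgraph, "w") as fh:
        for i, v in enumerate(values):
            fh.write(f"{cfg.chrom}\t{i}\t{i + 1}\t{v:.3f}\n")
    return {"residue_tracks": tracks, "domains": domains, "ptms": ptms,
            "conservation": bedgraph}


def make_assetseq_counts(cfg: SimConfig, cell_lines: tuple[str, ...] = ("cellA",)
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw reporter count tables from the interaction model.

    Returns (counts, truth): counts in the long table schema of the
    assetseq module; truth holds the planted interaction coefficient per
    variant.  NB dispersions below 1e-8 fall back to Poisson draws.
    """
    rng = cfg.rng("assetseq")
    counts_rows, truth_rows = [], []
    n_null = int(round(cfg.assetseq_n_isnv * cfg.assetseq_null_fraction))
    for i in range(cfg.assetseq_n_isnv):
        isnv = f"assay{i:03d}"
        if i < n_null:
            beta3 = 0.0
        else:
            beta3 = float(cfg.assetseq_beta3 * (1 if rng.random() < 0.5 else -1))
        truth_rows.append({"isnv": isnv, "beta3": beta3})
        for cell in cell_lines:
            b0 = float(np.log(cfg.assetseq_mean_depth))
            b1, b2 = 0.0, cfg.assetseq_aberrant_log_ratio
            u = rng.normal(0.0, cfg.assetseq_random_intercept_sd,
                           size=cfg.assetseq_replicates)
            for r in range(cfg.assetseq_replicates):
                for allele, a in (("ref", 0.0), ("alt", 1.0)):
                    for cls, s in (("spliced", 0.0), ("aberrant", 1.0)):
                        mu = np.exp(b0 + b1 * a + b2 * s + beta3 * a * s + u[r])
                        alpha = cfg.assetseq_dispersion
                        if alpha < 1e-8:
                            y = int(rng.poisson(mu))
                        else:
                            y = int(rng.negative_binomial(
                                1.0 / alpha, 1.0 / (1.0 + alpha * mu)))
                        counts_rows.append({
                            "isnv": isnv, "cell_line": cell,
                            "replicate": f"rep{r + 1}", "allele": allele,
                            "splice_class": cls, "count": y})
    return pd.DataFrame(counts_rows), pd.DataFrame(truth_rows)


def simulate_bundle(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Write the complete fixture set under one directory."""
    out = Path(outdir)
    paths = {}
    paths.update(make_reference_bundle(cfg, out))
    paths.update(make_variant_sets(cfg, out))
    paths.update(make_auxiliary_tracks(cfg, out))
    counts, truth = make_assetseq_counts(cfg)
    paths["assetseq_counts"] = out / "assetseq_counts.tsv"
    counts.to_csv(paths["assetseq_counts"], sep="\t", index=False)
    paths["assetseq_truth"] = out / "assetseq_truth.tsv"
    truth.to_csv(paths["assetseq_truth"], sep="\t", index=False)
    return paths
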