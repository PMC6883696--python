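"""Gene-model / variant loading and intronic-variant classification.

Coordinates are 1-based inclusive in the input formats (GTF/GFF3, VCF) and
0-based half-open internally; every user-facing output reverts to 1-based.
Intron positions carry no position 0: +1 is the first intronic base after a
donor junction, -1 the last intronic base before an acceptor junction, in
transcript orientation.  A variant is *on-ss* when it falls in the donor
window +1..+7 or the acceptor window -13..-1, and *off-ss* anywhere else
inside an intron.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

DONOR_WINDOW = (1, 7)      # intron positions downstream of the donor
ACCEPTOR_WINDOW = (-13, -1)  # intron positions upstream of the acceptor
NEARBY_BP = 300

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch(genome, chrom: str, start0: int, end0: int, strand: str = "+") -> str:
    """Extract genome sequence on [start0, end0), upper-cased; reverse
    complemented for strand '-'. ``genome`` is a pyfaidx.Fasta-like mapping."""
    seq = str(genome[chrom][start0:end0]).upper()
    return revcomp(seq) if strand == "-" else seq


class NotIntronicError(ValueError):
    """Variant does not lie strictly inside an intron of any transcript."""


@dataclass(frozen=True)
class GeneModel:
    """One transcript: ordered exons, CDS intervals, strand.

    Exons and CDS are 0-based half-open genomic intervals in ascending
    genomic order; transcript-ordered views flip for the minus strand.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        ex = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for (a, b) in ex:
            if not (0 <= a < b):
                raise ValueError(f"bad exon interval ({a}, {b})")
        for (a1, b1), (a2, b2) in zip(ex, ex[1:]):
            if a2 < b1:
                raise ValueError("overlapping exons")
        object.__setattr__(self, "exons", ex)
        object.__setattr__(self, "cds", tuple(sorted(self.cds)))

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_transcript_order(self) -> list[tuple[int, int]]:
        return list(self.exons) if self.strand == "+" else list(self.exons)[::-1]

    def introns_genomic(self) -> list[tuple[int, int]]:
        """Introns as 0-based half-open genomic intervals, ascending."""
        return [(b1, a2) for (_, b1), (a2, _) in zip(self.exons, self.exons[1:])]

    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV, 1-based position, with optional MAF."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    id: str | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError("ref/alt must be single bases in ACGT")
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if self.pos < 1:
            raise ValueError("position must be positive (1-based)")

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass(frozen=True)
class VariantContext:
    """A variant resolved against its transcript: junction geometry + class."""

    variant: Variant
    transcript_id: str
    strand: str
    exon_index: int            # transcript-order index of the nearest exon
    intron_index: int          # transcript-order index of the host intron
    donor_distance: int        # +1, +2, ... downstream of donor
    acceptor_distance: int     # ..., -2, -1 upstream of acceptor
    region_class: str          # "on-ss" | "off-ss"
    within_300bp: bool

    @property
    def min_distance(self) -> int:
        return min(self.donor_distance, -self.acceptor_distance)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _transcript_key(feature) -> str | None:
    attrs = feature.attributes
    for key in ("transcript_id", "Parent", "ID"):
        if key in attrs and attrs[key]:
            val = attrs[key][0]
            return val.split(":")[-1]  # GFF3 "transcript:ENST..." style
    return None


def load_gene_models(path) -> list[GeneModel]:
    """Parse exon and CDS records from a GTF or GFF3 file into GeneModels.

    Malformed records are skipped with a warning; a file yielding zero
    usable transcripts is an error.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception:
                logger.warning("%s:%d: unparseable record skipped", path, lineno)
                continue
            if feat.featuretype not in ("exon", "CDS"):
                continue
            if feat.end < feat.start or feat.start < 1:
                logger.warning("%s:%d: bad coordinates (end < start) skipped",
                               path, lineno)
                continue
            tid = _transcript_key(feat)
            if tid is None:
                logger.warning("%s:%d: no transcript id, skipped", path, lineno)
                continue
            gene = feat.attributes.get("gene_id", [""])[0]
            meta.setdefault(tid, (feat.seqid, feat.strand, gene))
            iv = (feat.start - 1, feat.end)  # to 0-based half-open
            (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)
    models = []
    for tid, ivs in exons.items():
        chrom, strand, gene = meta[tid]
        try:
            models.append(GeneModel(tid, chrom, strand, tuple(ivs),
                                    tuple(cds.get(tid, [])), gene))
        except ValueError as exc:
            logger.warning("transcript %s skipped: %s", tid, exc)
    if not models:
        raise ValueError(f"no usable transcripts in {path}")
    return models


def load_variants(vcf_path, genome, multiallelic: str = "split") -> list[Variant]:
    """Load biallelic SNVs from a VCF, verifying REF against the genome.

    ``multiallelic``: "split" emits one Variant per SNV ALT allele, "skip"
    drops multiallelic records.  Non-SNV records and REF mismatches are
    excluded with a warning.
    """
    from cyvcf2 import VCF

    out: list[Variant] = []
    for rec in VCF(str(vcf_path)):
        alts = rec.ALT
        if len(alts) > 1 and multiallelic == "skip":
            logger.warning("%s:%d multiallelic record skipped", rec.CHROM, rec.POS)
            continue
        if len(rec.REF) != 1 or rec.REF not in "ACGT":
            logger.warning("%s:%d non-SNV REF excluded", rec.CHROM, rec.POS)
            continue
        genome_base = fetch(genome, rec.CHROM, rec.POS - 1, rec.POS)
        if genome_base != rec.REF:
            logger.warning("%s:%d REF %s does not match genome %s; excluded",
                           rec.CHROM, rec.POS, rec.REF, genome_base)
            continue
        af = rec.INFO.get("AF")
        if isinstance(af, tuple):
            afs = list(af)
        elif af is None:
            afs = [None] * len(alts)
        else:
            afs = [af] * len(alts)
        for alt, maf in zip(alts, afs):
            if len(alt) != 1 or alt not in "ACGT":
                logger.warning("%s:%d ALT %s not an SNV; excluded",
                               rec.CHROM, rec.POS, alt)
                continue
            out.append(Variant(rec.CHROM, rec.POS, rec.REF, alt,
                               id=rec.ID, maf=float(maf) if maf is not None else None))
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _context_in_transcript(variant: Variant, model: GeneModel) -> VariantContext | None:
    """Context of ``variant`` within one transcript, or None if not intronic."""
    if model.chrom != variant.chrom:
        return None
    p = variant.pos0
    introns = model.introns_genomic()
    for gi, (istart, iend) in enumerate(introns):
        if not (istart <= p < iend):
            continue
        length = iend - istart
        if model.strand == "+":
            donor_d = p - istart + 1
            intron_idx = gi
        else:
            donor_d = iend - p
            intron_idx = len(introns) - 1 - gi
        acceptor_d = donor_d - length - 1  # in -1..-length
        on_ss = (DONOR_WINDOW[0] <= donor_d <= DONOR_WINDOW[1]
                 or ACCEPTOR_WINDOW[0] <= acceptor_d <= ACCEPTOR_WINDOW[1])
        # nearest exon: upstream of donor if donor side closer (ties donor-ward)
        if donor_d <= -acceptor_d:
            exon_idx = intron_idx
        else:
            exon_idx = intron_idx + 1
        return VariantContext(
            variant=variant, transcript_id=model.transcript_id,
            strand=model.strand, exon_index=exon_idx, intron_index=intron_idx,
            donor_distance=donor_d, acceptor_distance=acceptor_d,
            region_class="on-ss" if on_ss else "off-ss",
            within_300bp=min(donor_d, -acceptor_d) <= NEARBY_BP)
    return None


def classify_variant(variant: Variant, models: Sequence[GeneModel]) -> VariantContext:
    """Resolve a variant to its reported transcript context.

    Among all transcripts in which the variant is intronic, the reported
    context is the one minimising the junction distance; ties break toward
    the longest CDS, then the lexicographically smallest transcript id.
    Raises :class:`NotIntronicError` if no transcript hosts the variant
    inside an intron.
    """
    candidates: list[tuple[int, int, str, VariantContext]] = []
    for model in models:
        ctx = _context_in_transcript(variant, model)
        if ctx is not None:
            candidates.append((ctx.min_distance, -model.cds_length(),
                               model.transcript_id, ctx))
    if not candidates:
        raise NotIntronicError(
            f"{variant.chrom}:{variant.pos} {variant.ref}>{variant.alt} "
            "is not intronic in any transcript")
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    return candidates[0][3]


def classify_variants(variants: Iterable[Variant], models: Sequence[GeneModel]
                      ) -> list[VariantContext]:
    """Classify a collection, dropping non-intronic variants with a warning."""
    out = []
    for v in variants:
        try:
            out.append(classify_variant(v, models))
        except NotIntronicError:
            logger.warning("%s:%d not intronic; skipped", v.chrom, v.pos)
    return out


def contexts_to_table(contexts: Sequence[VariantContext]):
    """Tabulate contexts as a DataFrame with 1-based output coordinates."""
    import pandas as pd

    rows = []
    for c in contexts:
        v = c.variant
        rows.append(dict(
            variant_id=v.id or f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}",
            chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
            transcript=c.transcript_id, strand=c.strand,
            exon_index=c.exon_index, donor_distance=c.donor_distance,
            acceptor_distance=c.acceptor_distance,
            region_class=c.region_class, within_300bp=c.within_300bp,
            maf=v.maf))
    return pd.DataFrame(rows)
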