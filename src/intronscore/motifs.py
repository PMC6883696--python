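"""Splice-junction position weight matrices and junction scores.

Donor PWMs span positions -3..+7 around the exon|intron boundary (3 exonic
bases, 7 intronic, no position 0; 10 columns).  Acceptor PWMs span -13..+1
around the intron|exon boundary (13 intronic bases, 1 exonic; 14 columns).
The junction score of a window is the sum of pseudo-counted log2-odds over
its positions — the same scoring machinery used for RBP motifs — so higher
scores indicate stronger resemblance to annotated canonical junctions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotate import GeneModel, VariantContext, fetch, revcomp
from .rbp import ALPHABET, RbpPwm, matching_score

logger = logging.getLogger(__name__)

DONOR_EXONIC = 3
DONOR_INTRONIC = 7
ACCEPTOR_INTRONIC = 13
ACCEPTOR_EXONIC = 1


@dataclass(frozen=True)
class SpliceSitePwm:
    """Count matrix over a junction window, with the pseudo-count scheme
    c = sqrt(N) and uniform background 0.25 shared with RBP motifs."""

    site_type: str             # "donor" | "acceptor"
    counts: np.ndarray         # (window, 4)
    n_sites: float

    def __post_init__(self) -> None:
        if self.site_type not in ("donor", "acceptor"):
            raise ValueError("site_type must be 'donor' or 'acceptor'")
        expected = (DONOR_EXONIC + DONOR_INTRONIC if self.site_type == "donor"
                    else ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC)
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (expected, 4):
            raise ValueError(
                f"{self.site_type} window must have {expected} positions")
        object.__setattr__(self, "counts", counts)

    @property
    def offsets(self) -> list[int]:
        """Window positions relative to the junction (no position 0)."""
        if self.site_type == "donor":
            return list(range(-DONOR_EXONIC, 0)) + list(range(1, DONOR_INTRONIC + 1))
        return list(range(-ACCEPTOR_INTRONIC, 0)) + list(range(1, ACCEPTOR_EXONIC + 1))

    def window_length(self) -> int:
        return self.counts.shape[0]

    def log_odds(self) -> np.ndarray:
        return RbpPwm(self.site_type, self.counts, max(self.n_sites, 1)).log_odds()

    def index_of(self, offset: int) -> int:
        """Column index of a junction-relative position."""
        return self.offsets.index(offset)


def _donor_window_interval(istart: int, iend: int, strand: str) -> tuple[int, int]:
    """Genomic interval (0-based half-open) of the donor window of an intron."""
    if strand == "+":
        return istart - DONOR_EXONIC, istart + DONOR_INTRONIC
    return iend - DONOR_INTRONIC, iend + DONOR_EXONIC


def _acceptor_window_interval(istart: int, iend: int, strand: str) -> tuple[int, int]:
    if strand == "+":
        return iend - ACCEPTOR_INTRONIC, iend + ACCEPTOR_EXONIC
    return istart - ACCEPTOR_EXONIC, istart + ACCEPTOR_INTRONIC


def _extract(genome, chrom: str, start0: int, end0: int, strand: str) -> str | None:
    if start0 < 0:
        return None
    try:
        seq = fetch(genome, chrom, start0, end0, strand)
    except (KeyError, IndexError):
        return None
    if len(seq) != end0 - start0 or any(b not in ALPHABET for b in seq):
        return None
    return seq


def build_splice_pwms(models: Sequence[GeneModel], genome
                      ) -> tuple[SpliceSitePwm, SpliceSitePwm]:
    """Tally donor/acceptor windows over all annotated internal introns.

    Junctions shared by several transcripts are counted once (deduplicated
    by genomic coordinate and strand); windows running past a contig end
    are skipped with a warning.
    """
    donor_counts = np.zeros((DONOR_EXONIC + DONOR_INTRONIC, 4))
    acceptor_counts = np.zeros((ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC, 4))
    n_donor = n_acceptor = 0
    seen_d: set[tuple] = set()
    seen_a: set[tuple] = set()
    base_idx = {b: j for j, b in enumerate(ALPHABET)}
    for model in models:
        for (istart, iend) in model.introns_genomic():
            dkey = (model.chrom, model.strand,
                    istart if model.strand == "+" else iend)
            akey = (model.chrom, model.strand,
                    iend if model.strand == "+" else istart)
            if dkey not in seen_d:
                seen_d.add(dkey)
                s, e = _donor_window_interval(istart, iend, model.strand)
                seq = _extract(genome, model.chrom, s, e, model.strand)
                if seq is None:
                    logger.warning("donor window at %s:%d out of contig; skipped",
                                   model.chrom, istart)
                else:
                    for i, b in enumerate(seq):
                        donor_counts[i, base_idx[b]] += 1
                    n_donor += 1
            if akey not in seen_a:
                seen_a.add(akey)
                s, e = _acceptor_window_interval(istart, iend, model.strand)
                seq = _extract(genome, model.chrom, s, e, model.strand)
                if seq is None:
                    logger.warning("acceptor window at %s:%d out of contig; skipped",
                                   model.chrom, iend)
                else:
                    for i, b in enumerate(seq):
                        acceptor_counts[i, base_idx[b]] += 1
                    n_acceptor += 1
    if n_donor == 0 or n_acceptor == 0:
        raise ValueError("annotation contains no usable internal introns")
    return (SpliceSitePwm("donor", donor_counts, n_donor),
            SpliceSitePwm("acceptor", acceptor_counts, n_acceptor))


def junction_score(window_seq: str, pwm: SpliceSitePwm) -> float:
    """Log2-odds sum of a window sequence against a splice-site PWM (bits)."""
    return matching_score(window_seq, pwm.log_odds())


def exon_junction_scores(model: GeneModel, exon_index: int,
                         donor_pwm: SpliceSitePwm, acceptor_pwm: SpliceSitePwm,
                         genome) -> dict[str, float | None]:
    """Donor (3') and acceptor (5') junction scores flanking one exon.

    ``exon_index`` is in transcript order.  Terminal exons lack one of the
    junctions; the missing side is reported as None.
    """
    exons_t = model.exons_transcript_order()
    if not (0 <= exon_index < len(exons_t)):
        raise IndexError("exon index out of range")
    introns = model.introns_genomic()
    introns_t = introns if model.strand == "+" else introns[::-1]
    out: dict[str, float | None] = {"donor": None, "acceptor": None}
    # donor: junction at the 3' end of this exon -> intron exon_index
    if exon_index < len(introns_t):
        istart, iend = introns_t[exon_index]
        s, e = _donor_window_interval(istart, iend, model.strand)
        seq = _extract(genome, model.chrom, s, e, model.strand)
        if seq is not None:
            out["donor"] = junction_score(seq, donor_pwm)
    # acceptor: junction at the 5' end of this exon -> intron exon_index-1
    if exon_index > 0:
        istart, iend = introns_t[exon_index - 1]
        s, e = _acceptor_window_interval(istart, iend, model.strand)
        seq = _extract(genome, model.chrom, s, e, model.strand)
        if seq is not None:
            out["acceptor"] = junction_score(seq, acceptor_pwm)
    return out


def delta_junction_score(context: VariantContext, model: GeneModel,
                         donor_pwm: SpliceSitePwm, acceptor_pwm: SpliceSitePwm,
                         genome) -> dict[str, float | None]:
    """Alt-minus-ref junction score for the window(s) containing the variant.

    Defined only for on-ss variants; each side outside its window is None.
    The substitution is applied in transcript orientation (the variant base
    is complemented on minus-strand transcripts).
    """
    out: dict[str, float | None] = {"donor": None, "acceptor": None}
    if context.region_class != "on-ss":
        return out
    introns = model.introns_genomic()
    introns_t = introns if model.strand == "+" else introns[::-1]
    istart, iend = introns_t[context.intron_index]
    v = context.variant
    ref_t = v.ref if model.strand == "+" else revcomp(v.ref)
    alt_t = v.alt if model.strand == "+" else revcomp(v.alt)
    jobs = []
    if 1 <= context.donor_distance <= DONOR_INTRONIC:
        jobs.append(("donor", donor_pwm, _donor_window_interval(istart, iend, model.strand),
                     donor_pwm.index_of(context.donor_distance)))
    if -ACCEPTOR_INTRONIC <= context.acceptor_distance <= -1:
        jobs.append(("acceptor", acceptor_pwm,
                     _acceptor_window_interval(istart, iend, model.strand),
                     acceptor_pwm.index_of(context.acceptor_distance)))
    for side, pwm, (s, e), idx in jobs:
        seq = _extract(genome, model.chrom, s, e, model.strand)
        if seq is None:
            continue
        if seq[idx] != ref_t:
            logger.warning("window base %s != variant ref %s at %s:%d",
                           seq[idx], ref_t, v.chrom, v.pos)
        alt_seq = seq[:idx] + alt_t + seq[idx + 1:]
        out[side] = junction_score(alt_seq, pwm) - junction_score(seq, pwm)
    return out


# ---------------------------------------------------------------------------
# Serialization: TSV with metadata header rows then 4 count columns
# ---------------------------------------------------------------------------

def write_splice_pwms(donor: SpliceSitePwm, acceptor: SpliceSitePwm, path) -> None:
    with open(path, "w") as fh:
        for pwm in (donor, acceptor):
            fh.write(f">{pwm.site_type}\tN={pwm.n_sites:g}\t"
                     f"positions={','.join(map(str, pwm.offsets))}\n")
            for row in pwm.counts:
                fh.write("\t".join(f"{v:g}" for v in row) + "\n")


def read_splice_pwms(path) -> tuple[SpliceSitePwm, SpliceSitePwm]:
    blocks: dict[str, tuple[float, list[list[float]]]] = {}
    site, n, rows = None, 0.0, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if site is not None:
                    blocks[site] = (n, rows)
                fields = line[1:].split("\t")
                site = fields[0]
                n = next((float(f[2:]) for f in fields if f.startswith("N=")), 0.0)
                rows = []
            else:
                rows.append([float(x) for x in line.split()[:4]])
    if site is not None:
        blocks[site] = (n, rows)
    try:
        dn, drows = blocks["donor"]
        an, arows = blocks["acceptor"]
    except KeyError as exc:
        raise ValueError(f"missing PWM block in {path}") from exc
    return (SpliceSitePwm("donor", np.array(drows), dn),
            SpliceSitePwm("acceptor", np.array(arows), an))
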