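"""Assembly of the per-variant feature table from all feature extractors.

Every variant context contributes: the donor/acceptor junction scores of
its nearest exon; for on-ss variants the allele-induced junction-score
deltas; per-RBP binding-change magnitude (M) and switch probability (P);
eight structural features of the protein segment encoded by the nearest
exon; and three conservation features.  Features that cannot be computed
(no CDS, missing track, truncated flank) are emitted as NaN — downstream
models impute medians and carry absence flags, because zero is a
meaningful value for most of these scales.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import conservation as cons_mod
from . import protein as prot_mod
from .annotate import GeneModel, VariantContext, fetch, revcomp
from .conservation import ConservationTrack
from .motifs import SpliceSitePwm, delta_junction_score, exon_junction_scores
from .rbp import RbpScorer

logger = logging.getLogger(__name__)

META_COLUMNS = ["variant_id", "region_class", "label", "maf", "min_distance"]


def _allele_contexts(ctx: VariantContext, genome, flank: int
                     ) -> tuple[str, str] | None:
    """Ref/alt sequence contexts around the variant, transcript orientation."""
    v = ctx.variant
    start = max(v.pos0 - flank, 0)
    try:
        seq = fetch(genome, v.chrom, start, v.pos0 + flank + 1, "+")
    except (KeyError, IndexError):
        return None
    center = v.pos0 - start
    if center >= len(seq) or seq[center] != v.ref:
        logger.warning("genome base mismatch at %s:%d", v.chrom, v.pos)
        return None
    alt_seq = seq[:center] + v.alt + seq[center + 1:]
    if ctx.strand == "-":
        seq, alt_seq = revcomp(seq), revcomp(alt_seq)
    return seq, alt_seq


def extract_features(
    contexts: Sequence[VariantContext],
    models: Mapping[str, GeneModel],
    genome,
    donor_pwm: SpliceSitePwm,
    acceptor_pwm: SpliceSitePwm,
    rbp_scorer: RbpScorer | None = None,
    residue_tracks: Mapping[str, prot_mod.ResidueTrack] | None = None,
    domains: Mapping[str, prot_mod.DomainSet] | None = None,
    ptms: Mapping[str, prot_mod.PtmSet] | None = None,
    cons_track: ConservationTrack | None = None,
) -> pd.DataFrame:
    """One row per variant context; meta columns plus all feature columns."""
    max_k = max((p.k for p in rbp_scorer.pwms), default=0) if rbp_scorer else 0
    rows = []
    for ctx in contexts:
        v = ctx.variant
        model = models[ctx.transcript_id]
        row: dict[str, object] = {
            "variant_id": v.id or f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}",
            "region_class": ctx.region_class,
            "maf": v.maf if v.maf is not None else np.nan,
            "min_distance": ctx.min_distance,
        }
        js = exon_junction_scores(model, ctx.exon_index, donor_pwm,
                                  acceptor_pwm, genome)
        row["junction_donor"] = js["donor"] if js["donor"] is not None else np.nan
        row["junction_acceptor"] = (js["acceptor"]
                                    if js["acceptor"] is not None else np.nan)
        if ctx.region_class == "on-ss":
            delta = delta_junction_score(ctx, model, donor_pwm, acceptor_pwm, genome)
            row["delta_donor"] = (delta["donor"]
                                  if delta["donor"] is not None else np.nan)
            row["delta_acceptor"] = (delta["acceptor"]
                                     if delta["acceptor"] is not None else np.nan)
        if rbp_scorer is not None:
            pair = _allele_contexts(ctx, genome, max_k - 1) if max_k else None
            if pair is None:
                for pwm in rbp_scorer.pwms:
                    row[f"rbp_M_{pwm.name}"] = np.nan
                    row[f"rbp_P_{pwm.name}"] = np.nan
            else:
                for imp in rbp_scorer.impacts(*pair):
                    row[f"rbp_M_{imp.name}"] = imp.m
                    row[f"rbp_P_{imp.name}"] = imp.p
        if residue_tracks is not None:
            feats = {name: np.nan for name in prot_mod.FEATURE_NAMES}
            track = residue_tracks.get(ctx.transcript_id)
            interval = (prot_mod.map_exon_to_residues(model, ctx.exon_index)
                        if track is not None and model.cds else None)
            if track is not None and interval is not None:
                start, end = interval
                if 1 <= start <= end <= len(track):
                    feats = prot_mod.structural_features(
                        interval, track,
                        (domains or {}).get(ctx.transcript_id),
                        (ptms or {}).get(ctx.transcript_id)).as_dict()
            row.update(feats)
        if cons_track is not None:
            row.update(cons_mod.conservation_features(v, cons_track))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.insert(2, "label", pd.NA)
    return df


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in META_COLUMNS]
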