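"""End-to-end pipeline: bundle on disk -> features -> trained, calibrated models.

Glues the loaders, feature extractors and the classifier together the same
way the command-line interface does, so tests and scripted analyses can run
the full path (annotate -> features -> assemble -> train -> calibrate ->
predict -> evaluate) with one call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pyfaidx

from . import annotate, conservation, features, model, motifs, protein, rbp


@dataclass
class Bundle:
    """Loaded inputs: genome, gene models, motifs, tracks."""

    genome: pyfaidx.Fasta
    models: dict[str, annotate.GeneModel]
    donor_pwm: motifs.SpliceSitePwm
    acceptor_pwm: motifs.SpliceSitePwm
    rbp_scorer: rbp.RbpScorer | None = None
    residue_tracks: Mapping[str, protein.ResidueTrack] | None = None
    domains: Mapping[str, protein.DomainSet] | None = None
    ptms: Mapping[str, protein.PtmSet] | None = None
    cons_track: conservation.ConservationTrack | None = None


def load_bundle(directory, with_rbp: bool = True, with_tracks: bool = True
                ) -> Bundle:
    """Load a fixture/analysis directory written by the simulator (or with
    the same file names) and build splice PWMs from its annotation."""
    d = Path(directory)
    genome = pyfaidx.Fasta(str(d / "genome.fa"))
    gene_models = {m.transcript_id: m
                   for m in annotate.load_gene_models(d / "genes.gtf")}
    donor, acceptor = motifs.build_splice_pwms(list(gene_models.values()), genome)
    scorer = None
    if with_rbp and (d / "rbp_motifs.tsv").exists():
        scorer = rbp.RbpScorer(rbp.read_pwms(d / "rbp_motifs.tsv"))
    tracks = domains = ptms = cons = None
    if with_tracks:
        if (d / "residue_tracks.tsv").exists():
            tracks = protein.read_residue_tracks(d / "residue_tracks.tsv")
        if (d / "domains.tsv").exists():
            domains = protein.read_domains(d / "domains.tsv")
        if (d / "ptms.tsv").exists():
            ptms = protein.read_ptms(d / "ptms.tsv")
        if (d / "conservation.bedGraph").exists():
            cons = conservation.ConservationTrack.from_file(
                d / "conservation.bedGraph")
    return Bundle(genome, gene_models, donor, acceptor, scorer,
                  tracks, domains, ptms, cons)


def feature_table(bundle: Bundle, vcf_path) -> pd.DataFrame:
    """Load a VCF, classify intronic variants and extract all features."""
    variants = annotate.load_variants(vcf_path, bundle.genome)
    contexts = annotate.classify_variants(variants, list(bundle.models.values()))
    return features.extract_features(
        contexts, bundle.models, bundle.genome, bundle.donor_pwm,
        bundle.acceptor_pwm, bundle.rbp_scorer, bundle.residue_tracks,
        bundle.domains, bundle.ptms, bundle.cons_track)


@dataclass
class TrainedPipeline:
    datasets: dict[str, dict[str, model.FeatureMatrix]]
    models: dict[str, model.FprCalibratedForest]
    metrics: dict[str, dict[str, float]]
    predictions: dict[str, pd.DataFrame]


def train_and_evaluate(feature_df: pd.DataFrame, labels: pd.Series | Mapping,
                       seed: int = 0,
                       n_estimators_grid: Sequence[int] = (50, 100),
                       max_depth_grid: Sequence[int] = (5, 10, 15),
                       ) -> TrainedPipeline:
    """Assemble datasets, train + calibrate per region class, evaluate held out.

    ``labels`` maps variant_id -> {"pathogenic", "neutral"}.  The default
    hyperparameter grid is deliberately compact; pass the full grids from
    :mod:`intronscore.model` for an exhaustive search.
    """
    df = feature_df.copy()
    lab = pd.Series(labels)
    df["label"] = df["variant_id"].map(lab)
    if df["label"].isna().any():
        missing = df.loc[df["label"].isna(), "variant_id"].tolist()[:5]
        raise ValueError(f"variants without labels, e.g. {missing}")
    datasets = model.assemble_datasets(
        df[df["label"] == model.POSITIVE_LABEL].drop(columns="label"),
        df[df["label"] == model.NEGATIVE_LABEL].drop(columns="label"),
        seed=seed)
    trained, metrics, preds = {}, {}, {}
    for region, split in datasets.items():
        est = model.train(split["train"], seed=seed,
                          n_estimators_grid=n_estimators_grid,
                          max_depth_grid=max_depth_grid)
        model.calibrate_fpr(est, split["validation"])
        rec = est.predict_records(split["validation"])
        y_val = split["validation"].y
        m = model.evaluate(y_val, rec["probability"].to_numpy())
        neutral = rec[y_val == 0]
        m["damaging_fpr"] = float((neutral["category"] == "Damaging").mean())
        trained[region] = est
        metrics[region] = m
        preds[region] = rec
    return TrainedPipeline(datasets, trained, metrics, preds)
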