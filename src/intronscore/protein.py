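"""Aggregation of per-residue structural annotations over exon segments.

Disorder, secondary structure and solvent accessibility are consumed as
precomputed per-residue tracks; domain intervals and PTM positions as
annotation tables.  Features summarise the protein segment encoded by a
variant's nearest exon: structured exons (low disorder, buried, inside
domains) tend to be the ones whose mis-splicing is damaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel

#: residues with disorder below this are counted as structured
STRUCTURED_DISORDER_THRESHOLD = 0.5

#: DSSP 8-state to 3-state reduction
_SS8_TO_3 = {"H": "H", "G": "H", "I": "H",
             "E": "E", "B": "E",
             "T": "C", "S": "C", "C": "C", "-": "C", "L": "C"}


@dataclass(frozen=True)
class ResidueTrack:
    """Per-residue disorder, secondary structure (H/E/C) and ASA for one protein."""

    protein_id: str
    disorder: np.ndarray     # (L,) in [0, 1]
    ss: np.ndarray           # (L,) unicode H/E/C
    asa: np.ndarray          # (L,) unit-agnostic passthrough

    def __post_init__(self) -> None:
        d = np.asarray(self.disorder, dtype=float)
        ss = np.asarray([_SS8_TO_3.get(s.upper(), "C") for s in self.ss])
        a = np.asarray(self.asa, dtype=float)
        if not (len(d) == len(ss) == len(a)):
            raise ValueError("track arrays must have equal length")
        if len(d) == 0:
            raise ValueError("empty track")
        object.__setattr__(self, "disorder", d)
        object.__setattr__(self, "ss", ss)
        object.__setattr__(self, "asa", a)

    def __len__(self) -> int:
        return len(self.disorder)


@dataclass(frozen=True)
class DomainSet:
    """Domain intervals (1-based inclusive residue coordinates) per protein."""

    protein_id: str
    intervals: tuple[tuple[int, int, str], ...] = ()


@dataclass(frozen=True)
class PtmSet:
    """Post-translational-modification residue positions (1-based)."""

    protein_id: str
    positions: tuple[int, ...] = ()


@dataclass(frozen=True)
class ExonStructuralFeatures:
    mean_disorder: float
    longest_structured_run: int
    frac_helix: float
    frac_sheet: float
    frac_coil: float
    mean_asa: float
    domain_overlap_pct: float
    ptm_per_100aa: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_disorder": self.mean_disorder,
            "longest_structured_run": float(self.longest_structured_run),
            "frac_helix": self.frac_helix,
            "frac_sheet": self.frac_sheet,
            "frac_coil": self.frac_coil,
            "mean_asa": self.mean_asa,
            "domain_overlap_pct": self.domain_overlap_pct,
            "ptm_per_100aa": self.ptm_per_100aa,
        }


FEATURE_NAMES = list(ExonStructuralFeatures(0, 0, 0, 0, 0, 0, 0, 0).as_dict())


def map_exon_to_residues(model: GeneModel, exon_index: int) -> tuple[int, int] | None:
    """Residue interval (1-based inclusive) encoded by one exon.

    A residue belongs to the exon if at least one of its codon nucleotides
    lies in the exon's CDS portion, so split codons are attributed to both
    flanking exons.  Returns None for exons with no CDS overlap (UTR-only).
    """
    exons_t = model.exons_transcript_order()
    if not (0 <= exon_index < len(exons_t)):
        raise IndexError("exon index out of range")
    ex_start, ex_end = exons_t[exon_index]
    cds = list(model.cds) if model.strand == "+" else list(model.cds)[::-1]
    offset = 0  # CDS nucleotides 5' of this exon's CDS portion
    for (cstart, cend) in cds:
        ov_start, ov_end = max(cstart, ex_start), min(cend, ex_end)
        if ov_start < ov_end:
            length = ov_end - ov_start
            if model.strand == "+":
                before = ov_start - cstart
            else:
                before = cend - ov_end
            first_nt = offset + before          # 0-based CDS coordinate
            last_nt = first_nt + length - 1
            return first_nt // 3 + 1, last_nt // 3 + 1
        offset += cend - cstart
    return None


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def structural_features(residue_interval: tuple[int, int], track: ResidueTrack,
                        domains: DomainSet | None = None,
                        ptms: PtmSet | None = None,
                        disorder_threshold: float = STRUCTURED_DISORDER_THRESHOLD
                        ) -> ExonStructuralFeatures:
    """Aggregate a residue track over one exon's residue interval."""
    start, end = residue_interval
    if start < 1 or end > len(track) or end < start:
        raise ValueError(
            f"residue interval {residue_interval} outside protein of "
            f"length {len(track)}")
    sl = slice(start - 1, end)
    n = end - start + 1
    d = track.disorder[sl]
    ss = track.ss[sl]
    in_domain = np.zeros(n, dtype=bool)
    for (ds, de, _name) in (domains.intervals if domains else ()):
        lo, hi = max(ds, start), min(de, end)
        if lo <= hi:
            in_domain[lo - start:hi - start + 1] = True
    n_ptm = sum(1 for p in (ptms.positions if ptms else ()) if start <= p <= end)
    return ExonStructuralFeatures(
        mean_disorder=float(d.mean()),
        longest_structured_run=_longest_run(d < disorder_threshold),
        frac_helix=float(np.mean(ss == "H")),
        frac_sheet=float(np.mean(ss == "E")),
        frac_coil=float(np.mean(ss == "C")),
        mean_asa=float(track.asa[sl].mean()),
        domain_overlap_pct=100.0 * in_domain.mean(),
        ptm_per_100aa=100.0 * n_ptm / n,
    )


# ---------------------------------------------------------------------------
# File readers: plain TSV tables
# ---------------------------------------------------------------------------

def read_residue_tracks(path) -> dict[str, ResidueTrack]:
    """TSV columns: protein_id, residue (1-based), disorder, ss, asa."""
    df = pd.read_csv(path, sep="\t")
    tracks = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("residue")
        if not np.array_equal(grp["residue"].to_numpy(),
                              np.arange(1, len(grp) + 1)):
            raise ValueError(f"track for {pid} has gaps or duplicate residues")
        tracks[pid] = ResidueTrack(pid, grp["disorder"].to_numpy(),
                                   grp["ss"].astype(str).to_numpy(),
                                   grp["asa"].to_numpy())
    return tracks


def read_domains(path) -> dict[str, DomainSet]:
    """TSV columns: protein_id, start, end, name (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    return {pid: DomainSet(pid, tuple(sorted(
                (int(r.start), int(r.end), str(r.name_))
                for r in grp.rename(columns={"name": "name_"}).itertuples())))
            for pid, grp in df.groupby("protein_id", sort=False)}


def read_ptms(path) -> dict[str, PtmSet]:
    """TSV columns: protein_id, position, type."""
    df = pd.read_csv(path, sep="\t")
    return {pid: PtmSet(pid, tuple(sorted(set(int(p) for p in grp["position"]))))
            for pid, grp in df.groupby("protein_id", sort=False)}
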