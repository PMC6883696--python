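"""Base-wise evolutionary conservation features.

Reads sparse per-base conservation tracks (bedGraph, fixed/variable-step
wig, or bigWig when pyBigWig is importable) and extracts, per variant, the
locus score plus locus-centred window means: the 3-bp flank window covers 7
bases and the 7-bp flank window 15 bases, locus included by default.
Missing bases are ignored in the means; windows at contig edges truncate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .annotate import Variant

FLANKS = (3, 7)


@dataclass
class ConservationTrack:
    """Sparse per-base scores: per chromosome, interval starts/ends/values."""

    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    @classmethod
    def from_bedgraph(cls, path) -> "ConservationTrack":
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
        df = df[~df["chrom"].astype(str).str.startswith(("track", "browser"))]
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            out[str(chrom)] = (grp["start"].to_numpy(dtype=np.int64),
                               grp["end"].to_numpy(dtype=np.int64),
                               grp["value"].to_numpy(dtype=float))
        return cls(out)

    @classmethod
    def from_wig(cls, path) -> "ConservationTrack":
        """Parse fixedStep / variableStep wiggle text."""
        rows: dict[str, list[tuple[int, int, float]]] = {}
        mode = chrom = None
        start = step = span = 1
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                if line.startswith(("fixedStep", "variableStep")):
                    fields = dict(f.split("=") for f in line.split()[1:])
                    mode = line.split()[0]
                    chrom = fields["chrom"]
                    span = int(fields.get("span", 1))
                    if mode == "fixedStep":
                        start = int(fields["start"])
                        step = int(fields.get("step", 1))
                    continue
                if mode is None:
                    raise ValueError("wig data before any step declaration")
                if mode == "fixedStep":
                    rows.setdefault(chrom, []).append(
                        (start - 1, start - 1 + span, float(line)))
                    start += step
                else:
                    pos_s, val = line.split()[:2]
                    pos = int(pos_s)
                    rows.setdefault(chrom, []).append(
                        (pos - 1, pos - 1 + span, float(val)))
        out = {}
        for c, ivs in rows.items():
            ivs.sort()
            arr = np.array(ivs, dtype=float)
            out[c] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64),
                      arr[:, 2])
        return cls(out)

    @classmethod
    def from_bigwig(cls, path) -> "ConservationTrack":
        import pyBigWig

        bw = pyBigWig.open(str(path))
        out = {}
        for chrom, length in bw.chroms().items():
            ivs = bw.intervals(chrom, 0, length) or []
            arr = np.array(ivs, dtype=float).reshape(-1, 3)
            out[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64),
                          arr[:, 2])
        bw.close()
        return cls(out)

    @classmethod
    def from_file(cls, path) -> "ConservationTrack":
        p = str(path)
        if p.endswith((".bw", ".bigwig", ".bigWig")):
            return cls.from_bigwig(p)
        if p.endswith((".wig", ".wiggle")):
            return cls.from_wig(p)
        return cls.from_bedgraph(p)

    def values(self, chrom: str, start0: int, end0: int) -> np.ndarray:
        """Per-base values on [start0, end0); NaN where the track is silent."""
        out = np.full(end0 - start0, np.nan)
        if chrom not in self.intervals or end0 <= start0:
            return out
        starts, ends, vals = self.intervals[chrom]
        i = np.searchsorted(ends, start0, side="right")
        while i < len(starts) and starts[i] < end0:
            lo = max(int(starts[i]), start0)
            hi = min(int(ends[i]), end0)
            if lo < hi:
                out[lo - start0:hi - start0] = vals[i]
            i += 1
        return out


def conservation_features(variant: Variant, track: ConservationTrack,
                          include_locus: bool = True) -> dict[str, float]:
    """Locus score and mean scores over the 3-bp and 7-bp flank windows.

    Window means are NaN when every base in the window is missing from the
    track (and all three features are NaN for chromosomes absent from it).
    """
    p = variant.pos0
    out: dict[str, float] = {}
    locus = track.values(variant.chrom, p, p + 1)[0]
    out["cons_locus"] = float(locus)
    for flank in FLANKS:
        window = track.values(variant.chrom, max(p - flank, 0), p + flank + 1)
        if not include_locus:
            center = p - max(p - flank, 0)
            window = np.delete(window, center)
        val = np.nanmean(window) if np.any(np.isfinite(window)) else np.nan
        out[f"cons_mean_{flank}bp"] = float(val)
    return out


FEATURE_NAMES = ["cons_locus"] + [f"cons_mean_{f}bp" for f in FLANKS]
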