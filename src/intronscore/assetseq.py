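"""Splicing-reporter read counting and allele-by-splicing interaction test.

A minigene reporter carrying either allele of a variant yields spliced and
aberrant (including unspliced) transcripts; sequencing read counts per
(cell line, replicate, allele, splice class) quantify the splicing outcome.
Whether the alternative allele shifts the spliced:aberrant balance is
tested with a negative-binomial regression with a replicate random
intercept:

    log E(Y) = b0 + b1*x_allele + b2*x_splice + b3*x_allele:x_splice + u_rep

with x_allele = 1 for the alternative allele, x_splice = 1 for aberrant
transcripts, u_rep ~ Normal(0, sigma^2).  The Wald p-value of the
interaction b3 decides significance.  The marginal likelihood integrates
the random intercept by Gauss-Hermite quadrature; when the fitted
random-effect variance collapses to zero the model falls back to a
negative-binomial GLM with replicate fixed effects (recorded per result).

Small-sample convention: maximum likelihood underestimates the variance
parameters with a handful of replicates, so Wald statistics use standard
errors inflated by sqrt(n / (n - p)) (the usual ML-to-unbiased denominator
correction, p counting all estimated parameters) and a between-within t
reference with df = n - p_fixed - (replicates - 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["isnv", "cell_line", "replicate", "allele", "splice_class", "count"]
ALLELES = ("ref", "alt")
CLASSES = ("spliced", "aberrant")

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(25)
_GH_LOGW = np.log(_GH_WEIGHTS) - 0.5 * np.log(2 * np.pi) - \
    np.log(np.sum(_GH_WEIGHTS / np.sqrt(2 * np.pi)))  # normalised N(0,1) weights


def _nb_logpmf(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 log pmf with Var = mu + alpha*mu^2, valid for non-integer y
    (continuity-corrected counts)."""
    r = 1.0 / alpha
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))


@dataclass
class SplicingTestResult:
    isnv: str
    cell_line: str
    beta: np.ndarray            # (4,) intercept, allele, splice, interaction
    se_interaction: float       # small-sample corrected
    p_value: float
    log2_odds_ratio: float
    direction: int              # sign of the interaction estimate
    evaluable: bool
    fallback: bool = False      # fixed-effect NB GLM used
    sigma: float = np.nan       # random-intercept SD
    dispersion: float = np.nan  # NB alpha
    df: float = np.nan          # t reference degrees of freedom


def _design(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = (df["allele"].to_numpy() == "alt").astype(float)
    s = (df["splice_class"].to_numpy() == "aberrant").astype(float)
    X = np.column_stack([np.ones(len(df)), a, s, a * s])
    y = df["count"].to_numpy(dtype=float)
    groups = pd.factorize(df["replicate"])[0]
    return y, X, groups


def _glmm_negloglik(params: np.ndarray, y: np.ndarray, X: np.ndarray,
                    groups: np.ndarray, n_groups: int) -> float:
    beta, log_alpha, log_sigma = params[:4], params[4], params[5]
    alpha = np.exp(log_alpha)
    sigma = np.exp(log_sigma)
    eta = X @ beta
    u = sigma * _GH_NODES  # (Q,)
    mu = np.exp(eta[None, :] + u[:, None])  # (Q, n)
    lp = _nb_logpmf(y[None, :], mu, alpha)  # (Q, n)
    total = 0.0
    for g in range(n_groups):
        mask = groups == g
        per_node = lp[:, mask].sum(axis=1) + _GH_LOGW
        m = per_node.max()
        total += m + np.log(np.exp(per_node - m).sum())
    return -total


def _numeric_hessian(fun, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.zeros((n, n))
    f0 = fun(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return h


def _start_values(df: pd.DataFrame) -> np.ndarray:
    cell = df.groupby(["allele", "splice_class"])["count"].mean()
    m = {k: max(float(cell.get(k, 1.0)), 0.5) for k in
         [("ref", "spliced"), ("ref", "aberrant"),
          ("alt", "spliced"), ("alt", "aberrant")]}
    b0 = np.log(m[("ref", "spliced")])
    b1 = np.log(m[("alt", "spliced")]) - b0
    b2 = np.log(m[("ref", "aberrant")]) - b0
    b3 = (np.log(m[("alt", "aberrant")]) - np.log(m[("alt", "spliced")])
          - np.log(m[("ref", "aberrant")]) + np.log(m[("ref", "spliced")]))
    return np.array([b0, b1, b2, b3, np.log(0.1), np.log(0.2)])


def _fit_fixed_effects(df: pd.DataFrame) -> tuple[np.ndarray, float, float, float]:
    """NB GLM with replicate fixed effects (statsmodels MLE of dispersion).

    When the dispersion collapses toward zero the NB optimiser may stall at
    the boundary; the Poisson GLM is then the correct limiting model and is
    used instead.
    """
    import statsmodels.api as sm

    y, X, groups = _design(df)
    n_groups = groups.max() + 1
    dummies = np.eye(n_groups)[groups][:, 1:]  # first replicate as baseline
    exog = np.column_stack([X, dummies])
    pois = sm.GLM(y, exog, family=sm.families.Poisson()).fit()
    with np.errstate(all="ignore"):
        try:
            res = sm.NegativeBinomial(y, exog).fit(
                disp=False, maxiter=200,
                start_params=np.append(pois.params, 0.05))
            converged = res.mle_retvals.get("converged", True)
        except Exception:
            converged = False
    if converged and np.isfinite(res.bse[3]):
        return (res.params[:4], float(res.bse[3]), float(res.pvalues[3]),
                float(res.params[-1]))
    return (pois.params[:4], float(pois.bse[3]), float(pois.pvalues[3]), 0.0)


def log2_odds_ratio(counts: pd.DataFrame) -> float:
    """log2[(ref spliced / ref aberrant) / (alt spliced / alt aberrant)]
    on replicate-pooled counts, with +0.5 continuity when any cell is zero."""
    pooled = counts.groupby(["allele", "splice_class"])["count"].sum()
    cells = {}
    for al in ALLELES:
        for cl in CLASSES:
            cells[(al, cl)] = float(pooled.get((al, cl), 0.0))
    if any(v == 0.0 for v in cells.values()):
        cells = {k: v + 0.5 for k, v in cells.items()}
    return float(np.log2((cells[("ref", "spliced")] / cells[("ref", "aberrant")])
                         / (cells[("alt", "spliced")] / cells[("alt", "aberrant")])))


def fit_splicing_model(counts: pd.DataFrame, sigma_floor: float = 1e-3
                       ) -> SplicingTestResult:
    """Fit the interaction model for one variant in one cell line.

    ``counts`` holds one row per (replicate, allele, splice class).  Raises
    on fewer than two replicates or missing allele-class cells; returns a
    non-evaluable result if neither the mixed nor the fixed-effect fit
    converges.
    """
    isnv = str(counts["isnv"].iloc[0])
    cell = str(counts["cell_line"].iloc[0])
    if counts["replicate"].nunique() < 2:
        raise ValueError("at least two replicates are required")
    present = set(map(tuple, counts[["allele", "splice_class"]].drop_duplicates()
                      .itertuples(index=False)))
    needed = {(a, c) for a in ALLELES for c in CLASSES}
    if not needed <= present:
        raise ValueError(f"missing allele/class cells: {sorted(needed - present)}")

    # canonical row order: results do not depend on input row order
    counts = counts.sort_values(
        ["replicate", "allele", "splice_class"]).reset_index(drop=True)
    pooled = counts.groupby(["allele", "splice_class"])["count"].sum()
    zero_cells = [k for k in needed if float(pooled.get(k, 0.0)) == 0.0]
    if zero_cells:
        logger.warning("%s/%s: zero cells %s; adding 0.5 continuity counts",
                       isnv, cell, zero_cells)
        counts["count"] = counts["count"].astype(float) + 0.5

    y, X, groups = _design(counts)
    n_obs = len(y)
    n_groups = int(groups.max()) + 1
    x0 = _start_values(counts)
    bounds = [(None, None)] * 4 + [(-12.0, 5.0), (-8.0, 3.0)]
    l2or = log2_odds_ratio(counts)
    df_bw = max(n_obs - X.shape[1] - (n_groups - 1), 1)

    def corrected_test(beta3: float, se3_raw: float, p_total: int
                       ) -> tuple[float, float]:
        inflation = np.sqrt(n_obs / max(n_obs - p_total, 1))
        se3 = se3_raw * inflation
        pval = float(2.0 * stats.t.sf(abs(beta3 / se3), df_bw))
        return se3, pval

    def make_result(beta, se3, pval, sigma, alpha, fallback):
        return SplicingTestResult(
            isnv=isnv, cell_line=cell, beta=np.asarray(beta, dtype=float),
            se_interaction=se3, p_value=pval, log2_odds_ratio=l2or,
            direction=int(np.sign(beta[3])) if np.isfinite(beta[3]) else 0,
            evaluable=True, fallback=fallback, sigma=sigma, dispersion=alpha,
            df=float(df_bw))

    try:
        with np.errstate(all="ignore"):
            opt = optimize.minimize(
                _glmm_negloglik, x0, args=(y, X, groups, n_groups),
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-11})
        sigma_hat = float(np.exp(opt.x[5]))
        alpha_hat = float(np.exp(opt.x[4]))
        if opt.success and sigma_hat > sigma_floor:
            with np.errstate(all="ignore"):
                hess = _numeric_hessian(
                    lambda p: _glmm_negloglik(p, y, X, groups, n_groups), opt.x)
                cov = np.linalg.inv(hess)
            se3_raw = float(np.sqrt(cov[3, 3])) if cov[3, 3] > 0 else np.nan
            if np.isfinite(se3_raw):
                se3, pval = corrected_test(opt.x[3], se3_raw, p_total=6)
                return make_result(opt.x[:4], se3, pval, sigma_hat, alpha_hat, False)
        raise RuntimeError("mixed fit degenerate")
    except (RuntimeError, np.linalg.LinAlgError):
        pass
    try:
        beta, se3_raw, _pval, alpha = _fit_fixed_effects(counts)
        se3, pval = corrected_test(beta[3], se3_raw,
                                   p_total=X.shape[1] + n_groups)
        return make_result(beta, se3, pval, 0.0, alpha, True)
    except Exception as exc:
        logger.warning("%s/%s non-evaluable: %s", isnv, cell, exc)
        return SplicingTestResult(
            isnv=isnv, cell_line=cell, beta=np.full(4, np.nan),
            se_interaction=np.nan, p_value=np.nan, log2_odds_ratio=l2or,
            direction=0, evaluable=False)


def fit_all(counts: pd.DataFrame) -> list[SplicingTestResult]:
    """Fit every (variant, cell line) group of a count table."""
    out = []
    for (_isnv, _cell), grp in counts.groupby(["isnv", "cell_line"], sort=True):
        try:
            out.append(fit_splicing_model(grp))
        except ValueError as exc:
            logger.warning("%s/%s skipped: %s", _isnv, _cell, exc)
    return out


def summarize_experiment(results: Sequence[SplicingTestResult],
                         fdr: float = 0.1) -> dict:
    """Per-cell-line validation rates (BH-FDR within cell line) and
    cross-cell-line concordance of log2 odds ratios."""
    df = pd.DataFrame([{
        "isnv": r.isnv, "cell_line": r.cell_line, "p_value": r.p_value,
        "log2_odds_ratio": r.log2_odds_ratio, "direction": r.direction,
        "evaluable": r.evaluable, "fallback": r.fallback} for r in results])
    df["q_value"] = np.nan
    df["significant"] = False
    rows = []
    for cell, grp in df.groupby("cell_line", sort=True):
        ev = grp[grp["evaluable"] & np.isfinite(grp["p_value"])]
        if len(ev):
            q = multipletests(ev["p_value"].to_numpy(), method="fdr_bh")[1]
            df.loc[ev.index, "q_value"] = q
            sig = q <= fdr
            df.loc[ev.index, "significant"] = sig
            rate = 100.0 * sig.mean()
        else:
            rate = np.nan
            logger.warning("cell line %s has no evaluable assays", cell)
        rows.append({"cell_line": cell, "n_evaluable": int(len(ev)),
                     "n_significant": int(df.loc[ev.index, "significant"].sum())
                     if len(ev) else 0,
                     "validation_rate_pct": rate})
    summary = pd.DataFrame(rows)
    cells = sorted(df["cell_line"].unique())
    conc = pd.DataFrame(np.nan, index=cells, columns=cells)
    wide = (df[df["evaluable"]]
            .pivot_table(index="isnv", columns="cell_line",
                         values="log2_odds_ratio"))
    for i, c1 in enumerate(cells):
        for c2 in cells[i:]:
            if c1 in wide and c2 in wide:
                both = wide[[c1, c2]].dropna()
                if len(both) >= 2:
                    r = float(np.corrcoef(both[c1], both[c2])[0, 1])
                    conc.loc[c1, c2] = conc.loc[c2, c1] = r
    return {"per_assay": df, "per_cell_line": summary, "concordance": conc}


# ---------------------------------------------------------------------------
# Read classification (reference matching in place of spliced alignment)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstructReference:
    """Expected transcript sequences for one variant allele construct."""

    isnv: str
    allele: str           # "ref" | "alt"
    spliced: str
    unspliced: str


def demultiplex_and_classify(reads: Iterable[str] | str,
                             constructs: Sequence[ConstructReference],
                             barcode_map: Mapping[str, tuple[str, str]],
                             max_mismatch: int = 2) -> pd.DataFrame:
    """Assign reads to (cell line, replicate, variant, allele, class).

    Reads start with a 6-nt sample barcode (exact match against
    ``barcode_map``) followed by the transcript sequence, which is matched
    by edit distance against every construct's spliced and unspliced
    references; the best match wins if within ``max_mismatch``.  Returns a
    complete long count table (zero-filled); unassignable reads are counted
    as discarded in the table's ``attrs``.
    """
    import edlib

    if len(set(barcode_map)) != len(barcode_map):
        raise ValueError("duplicate sample barcodes")
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ValueError("barcode collision: two barcodes map to one sample")
    blen = len(next(iter(barcode_map)))
    if any(len(b) != blen for b in barcode_map):
        raise ValueError("sample barcodes must share one length")

    refs = [(c.isnv, c.allele, cls, getattr(c, cls if cls != "aberrant" else "unspliced"))
            for c in constructs for cls in ("spliced", "unspliced")]

    if isinstance(reads, str):
        from Bio import SeqIO
        fmt = "fastq" if str(reads).endswith(("fastq", "fq")) else "fasta"
        reads = (str(rec.seq) for rec in SeqIO.parse(reads, fmt))

    counts: dict[tuple, int] = {}
    discarded = 0
    for read in reads:
        sample = barcode_map.get(read[:blen].upper())
        if sample is None:
            discarded += 1
            continue
        body = read[blen:].upper()
        best, best_d = None, max_mismatch + 1
        for isnv, allele, cls, ref in refs:
            d = edlib.align(body, ref, mode="NW", k=best_d)["editDistance"]
            if d != -1 and d < best_d:
                best, best_d = (isnv, allele, cls), d
        if best is None:
            discarded += 1
            continue
        isnv, allele, cls = best
        splice_class = "spliced" if cls == "spliced" else "aberrant"
        key = (isnv, sample[0], sample[1], allele, splice_class)
        counts[key] = counts.get(key, 0) + 1

    rows = []
    samples = sorted(set(barcode_map.values()))
    isnvs = sorted(set(c.isnv for c in constructs))
    for isnv in isnvs:
        for (cell, rep) in samples:
            for allele in ALLELES:
                for cls in CLASSES:
                    rows.append({"isnv": isnv, "cell_line": cell,
                                 "replicate": rep, "allele": allele,
                                 "splice_class": cls,
                                 "count": counts.get((isnv, cell, rep, allele, cls), 0)})
    table = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    table.attrs["discarded_reads"] = discarded
    return table


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"replicate": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
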