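"""RNA-binding-protein motif scoring and binding-switch probability.

For each RBP position-weight matrix two quantities describe how a single
nucleotide substitution changes predicted binding:

* the **M value** — the log2 ratio of binding-vs-nonbinding likelihood
  ratios (Omega) between the alternative and reference alleles, a signed
  magnitude in bits;
* **P(Switch)** — the posterior probability that the locus changes between
  a binding and a non-binding state, obtained by integrating a beta prior
  on the (unknown) base rate of binding sites against a closed-form
  conditional probability built from four Gaussian CDF values.

Matching scores are classic log-odds sums over a pseudo-counted PWM.  Their
distributions under the "binding" background (PWM frequencies) and the
"non-binding" background (uniform 1/4) are approximated as Gaussians whose
moments come directly from the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import integrate, optimize, stats
from scipy.special import betainc

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
#: uniform background frequency for every base
BACKGROUND = 0.25
#: floor applied to Omega when the survival function underflows
OMEGA_FLOOR = 1e-300


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[b] for b in seq.upper().replace("U", "T")),
                           dtype=np.intp, count=len(seq))
    except KeyError as exc:  # ambiguous base
        raise ValueError(f"non-ACGT base in sequence {seq!r}") from exc


@dataclass(frozen=True)
class RbpPwm:
    """A nucleotide count matrix for one RBP binding motif.

    ``counts[i, j]`` is the number of times base ``ACGT[j]`` was observed at
    motif position ``i`` among the ``n_sites`` sequences used to build the
    matrix.  The pseudo-count is ``sqrt(n_sites)`` per cell.
    """

    name: str
    counts: np.ndarray  # (k, 4) float array
    n_sites: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be a (k, 4) matrix over A,C,G,T")
        if counts.shape[0] < 1:
            raise ValueError("motif length must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        object.__setattr__(self, "counts", counts)

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def pseudo_count(self) -> float:
        return float(np.sqrt(self.n_sites))

    def binding_frequencies(self) -> np.ndarray:
        """Pseudo-counted base frequencies f_ij = (n+c)/(N + 4c)."""
        c = self.pseudo_count
        return (self.counts + c) / (self.n_sites + 4.0 * c)

    def log_odds(self) -> np.ndarray:
        """Log2 odds s_ij of the pseudo-counted frequency over 0.25."""
        return np.log2(self.binding_frequencies() / BACKGROUND)

    def information_content(self) -> float:
        """Sum over positions of 2 + sum_j f log2 f, with pseudo-counted f."""
        f = self.binding_frequencies()
        return float(np.sum(2.0 + np.sum(f * np.log2(f), axis=1)))

    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in np.argmax(self.counts, axis=1))


def matching_score(sequence: str, log_odds: np.ndarray) -> float:
    """Sum of per-position log-odds for a sequence of length k."""
    idx = _encode(sequence)
    if idx.size != log_odds.shape[0]:
        raise ValueError(
            f"sequence length {idx.size} != motif length {log_odds.shape[0]}")
    return float(log_odds[np.arange(idx.size), idx].sum())


@dataclass(frozen=True)
class ScoreDistribution:
    """Gaussian approximation of matching scores under one background."""

    background: Literal["B", "NB"]
    mean: float
    variance: float


def score_distribution(
    pwm: RbpPwm,
    background: Literal["B", "NB"],
    variance: Literal["per_cell", "per_position"] = "per_cell",
) -> ScoreDistribution:
    """Moments of the matching score under binding / non-binding backgrounds.

    ``variance="per_cell"`` follows the source formulation
    ``sum_ij (f s^2 - (f s)^2)``; ``"per_position"`` is the textbook variance
    of a sum of independent per-position draws.
    """
    s = pwm.log_odds()
    if background == "B":
        f = pwm.binding_frequencies()
    elif background == "NB":
        f = np.full_like(s, BACKGROUND)
    else:
        raise ValueError("background must be 'B' or 'NB'")
    mean = float(np.sum(f * s))
    if variance == "per_cell":
        var = float(np.sum(f * s**2 - (f * s) ** 2))
    elif variance == "per_position":
        var = float(np.sum(np.sum(f * s**2, axis=1) - np.sum(f * s, axis=1) ** 2))
    else:
        raise ValueError("variance must be 'per_cell' or 'per_position'")
    return ScoreDistribution(background, mean, var)


def phi(score: float, dist: ScoreDistribution) -> float:
    """Gaussian CDF of a matching score under the given background.

    Degenerate (zero-variance) distributions use a step convention with
    phi = 0.5 exactly at the mean.
    """
    if dist.variance <= 0.0:
        if score > dist.mean:
            return 1.0
        if score < dist.mean:
            return 0.0
        return 0.5
    return float(stats.norm.cdf(score, loc=dist.mean, scale=np.sqrt(dist.variance)))


def _log_omega(score: float, dist_b: ScoreDistribution,
               dist_nb: ScoreDistribution) -> float:
    """Natural log of Omega(S) = Phi(S,B) / (1 - Phi(S,NB)).

    Evaluated with logcdf / logsf so strong motifs do not overflow; an
    underflowing denominator clamps Omega at ``OMEGA_FLOOR``.
    """
    sd_b = np.sqrt(max(dist_b.variance, 0.0))
    sd_nb = np.sqrt(max(dist_nb.variance, 0.0))
    if sd_b == 0.0 or sd_nb == 0.0:
        num = phi(score, dist_b)
        den = 1.0 - phi(score, dist_nb)
        num = max(num, OMEGA_FLOOR)
        den = max(den, OMEGA_FLOOR)
        return float(np.log(num) - np.log(den))
    log_num = stats.norm.logcdf(score, loc=dist_b.mean, scale=sd_b)
    log_den = stats.norm.logsf(score, loc=dist_nb.mean, scale=sd_nb)
    log_floor = np.log(OMEGA_FLOOR)
    lo = log_num - log_den
    return float(np.clip(lo, log_floor, -log_floor))


def omega(score: float, dist_b: ScoreDistribution,
          dist_nb: ScoreDistribution) -> float:
    """Binding-vs-nonbinding likelihood ratio Omega(S), floored at 1e-300."""
    return float(np.exp(_log_omega(score, dist_b, dist_nb)))


def m_value(score_alt: float, score_ref: float, dist_b: ScoreDistribution,
            dist_nb: ScoreDistribution) -> float:
    """M = log2 Omega(S_alt) - log2 Omega(S_ref), in bits."""
    la = _log_omega(score_alt, dist_b, dist_nb)
    lr = _log_omega(score_ref, dist_b, dist_nb)
    return float((la - lr) / np.log(2.0))


@dataclass(frozen=True)
class BetaPrior:
    """Beta prior on the base rate x of true binding sites.

    The shape parameters satisfy alpha, beta > 1, place the mode at
    ``1 / 2**ic`` and put probability 0.005 below mode/10.
    """

    alpha: float
    beta: float
    mode: float


def _beta_from_alpha(alpha: float, mode: float) -> float:
    # eliminate beta via the mode identity (alpha-1)/(alpha+beta-2) = mode
    return 1.0 + (alpha - 1.0) * (1.0 - mode) / mode


def solve_beta_prior(ic: float, tail_level: float = 0.005) -> BetaPrior:
    """Solve the beta-prior shape parameters for a PWM of information content ic.

    Along the mode-constrained curve beta(alpha) the CDF at mode/10 rises to
    a single maximum and then decreases towards zero; the root is taken on
    the decreasing branch, where it is unique.
    """
    if ic <= 0:
        raise ValueError("information content must be > 0 (mode < 1)")
    mode = float(2.0 ** -ic)

    def cdf_at_tail(alpha: float) -> float:
        return float(betainc(alpha, _beta_from_alpha(alpha, mode), mode / 10.0))

    grid = 1.0 + np.logspace(-6, 6, 600)
    vals = np.array([cdf_at_tail(a) for a in grid])
    i_max = int(np.argmax(vals))
    if vals[i_max] < tail_level:
        raise ValueError(
            f"no (alpha, beta) with alpha, beta > 1 reaches CDF(mode/10) = "
            f"{tail_level} (max attainable {vals[i_max]:.3g}); "
            "tail-level constraint unsatisfiable for this IC")
    lo = grid[i_max]
    hi = grid[-1]
    if cdf_at_tail(hi) > tail_level:
        raise ValueError("tail constraint has no root on the searched bracket")
    alpha = optimize.brentq(lambda a: cdf_at_tail(a) - tail_level, lo, hi,
                            xtol=1e-12, rtol=8.9e-16)
    return BetaPrior(alpha=float(alpha), beta=float(_beta_from_alpha(alpha, mode)),
                     mode=mode)


def p_switch_conditional(x: np.ndarray, phi_r_b: float, phi_r_nb: float,
                         phi_a_b: float, phi_a_nb: float) -> np.ndarray:
    """P(Switch | x): probability the two alleles fall in different states
    given binding base rate x, from the four Gaussian CDF values."""
    x = np.asarray(x, dtype=float)
    num = x * (1.0 - x) * (phi_r_b * phi_a_nb + phi_r_nb * phi_a_b)
    den = ((x * phi_r_b + (1.0 - x) * phi_r_nb)
           * (x * phi_a_b + (1.0 - x) * phi_a_nb))
    out = np.zeros_like(x)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def p_switch(score_alt: float, score_ref: float, dist_b: ScoreDistribution,
             dist_nb: ScoreDistribution, prior: BetaPrior,
             tol: float = 1e-6) -> float:
    """Posterior switch probability, integrating P(Switch|x) over the beta prior.

    Uses adaptive quadrature to absolute tolerance ``tol``; a non-convergent
    integral falls back to composite Simpson on a fixed grid.
    """
    phis = (phi(score_ref, dist_b), phi(score_ref, dist_nb),
            phi(score_alt, dist_b), phi(score_alt, dist_nb))
    dens = stats.beta(prior.alpha, prior.beta)

    def integrand(x: float) -> float:
        return float(p_switch_conditional(np.array([x]), *phis)[0] * dens.pdf(x))

    try:
        val, _err = integrate.quad(integrand, 0.0, 1.0, epsabs=tol, limit=200)
    except Exception:
        val = np.nan
    if not np.isfinite(val):
        xs = np.linspace(0.0, 1.0, 4097)
        val = float(integrate.simpson(
            p_switch_conditional(xs, *phis) * dens.pdf(xs), x=xs))
    return float(min(max(val, 0.0), 1.0))


@dataclass(frozen=True)
class RbpImpact:
    """Per-RBP effect of one variant: allele scores, M value, P(Switch)."""

    name: str
    score_ref: float
    score_alt: float
    m: float
    p: float


class RbpScorer:
    """Scores variants against a collection of RBP PWMs.

    Caches the per-PWM log-odds, score distributions and beta priors so a
    collection can be applied to many variants cheaply.
    """

    def __init__(self, pwms: Sequence[RbpPwm],
                 variance: Literal["per_cell", "per_position"] = "per_cell",
                 window: Literal["best_per_allele", "best_of_ref"] = "best_per_allele"):
        self.pwms = list(pwms)
        self.window = window
        self._cache = []
        for pwm in self.pwms:
            lom = pwm.log_odds()
            dist_b = score_distribution(pwm, "B", variance)
            dist_nb = score_distribution(pwm, "NB", variance)
            prior = solve_beta_prior(max(pwm.information_content(), 1e-6))
            self._cache.append((lom, dist_b, dist_nb, prior))

    def _allele_scores(self, ref_seq: str, alt_seq: str, lom: np.ndarray
                       ) -> tuple[float, float]:
        """Best matching score per allele over all k-windows covering the locus.

        ``ref_seq``/``alt_seq`` are the two allele versions of the local
        context (identical except at one position); windows are maximised
        independently per allele, or jointly on the reference when
        ``window="best_of_ref"``.
        """
        k = lom.shape[0]
        if len(ref_seq) != len(alt_seq):
            raise ValueError("ref and alt context must have equal length")
        n_win = len(ref_seq) - k + 1
        if n_win < 1:
            raise ValueError("context shorter than motif")
        ref_scores = [matching_score(ref_seq[i:i + k], lom) for i in range(n_win)]
        alt_scores = [matching_score(alt_seq[i:i + k], lom) for i in range(n_win)]
        if self.window == "best_of_ref":
            i = int(np.argmax(ref_scores))
            return ref_scores[i], alt_scores[i]
        return max(ref_scores), max(alt_scores)

    def impacts(self, ref_context: str, alt_context: str) -> list[RbpImpact]:
        """Score one variant (given both allele contexts, transcript strand)."""
        out = []
        for pwm, (lom, dist_b, dist_nb, prior) in zip(self.pwms, self._cache):
            k = pwm.k
            if len(ref_context) < k:
                out.append(RbpImpact(pwm.name, np.nan, np.nan, np.nan, np.nan))
                continue
            s_r, s_a = self._allele_scores(ref_context, alt_context, lom)
            m = m_value(s_a, s_r, dist_b, dist_nb)
            p = p_switch(s_a, s_r, dist_b, dist_nb, prior)
            out.append(RbpImpact(pwm.name, s_r, s_a, m, p))
        return out


# ---------------------------------------------------------------------------
# PWM file I/O: simple TSV count matrices (name, k, N, then k rows of 4)
# ---------------------------------------------------------------------------

def read_pwms(path, default_n_sites: float = 100.0) -> list[RbpPwm]:
    """Read RBP count matrices from a TSV file.

    Format: blocks starting with a header line ``>name N=<sites>`` (N
    optional, default 100) followed by k lines of four whitespace-separated
    counts (A C G T).  RNA alphabets are transliterated on load.
    """
    pwms: list[RbpPwm] = []
    name, n_sites, rows = None, default_n_sites, []

    def flush():
        if name is not None:
            pwms.append(RbpPwm(name, np.array(rows, dtype=float), n_sites))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                name = parts[0]
                n_sites = default_n_sites
                rows = []
                for p in parts[1:]:
                    if p.startswith("N="):
                        n_sites = float(p[2:])
            else:
                rows.append([float(x) for x in line.split()[:4]])
    flush()
    if not pwms:
        raise ValueError(f"no PWMs found in {path}")
    return pwms


def write_pwms(pwms: Iterable[RbpPwm], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name} N={pwm.n_sites:g}\n")
            for row in pwm.counts:
                fh.write("\t".join(f"{v:g}" for v in row) + "\n")
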