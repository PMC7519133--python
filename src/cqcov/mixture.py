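"""Coverage-histogram decomposition and duplication-corrected genome size.

A genome carrying collapsed duplications — regions present twice per haploid
genome but assembled into a single contig — shows a bimodal per-contig
coverage distribution: an ordinary 1X mode and a second mode at twice its
depth.  This module formalises the visual reading of such a histogram:

1. fit 1- and 2-component Gaussian mixtures to log2(coverage), weighting
   each contig by its length, with a variance tied across components
   (two copy-number states of the same sequencing noise process);
2. choose the number of components by BIC;
3. for a bimodal fit, place the 1X/2X cutoff where the two weighted
   component densities are equal (between the means) and estimate the
   duplication-corrected genome size as ``bases_1x + 2 * bases_2x``.

Contigs with coverage above ``max_cov`` (default 100,000) are excluded from
the fit as mapping artifacts, and contigs below a small fraction of the
weighted median coverage (default 0.25) are excluded as well, so the
decomposition addresses the main component of the distribution rather than
the near-zero tail (unsequenced or sex-limited material).  Excluded contigs
still take part in the 1X/2X side assignment for the genome-size estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

log = logging.getLogger(__name__)

MAX_COVERAGE = 100_000.0
_SD_FLOOR = 1e-6
NOT_CONSISTENT = "NOT_CONSISTENT_WITH_DUPLICATION"

_LOG2 = math.log(2.0)


def build_histogram(counts) -> pd.DataFrame:
    """Per-contig coverage histogram (contig, coverage, length) from counts."""
    return pd.DataFrame({
        "contig": counts.counts.index,
        "coverage": counts.coverage().to_numpy(),
        "length": counts.lengths.to_numpy(),
    })


@dataclass
class MixtureFit:
    """A 1- or 2-component log-normal coverage decomposition."""

    n_components: int
    means: tuple[float, ...]        # component modes, coverage units (2**mu)
    sds: tuple[float, ...]          # delta-method sds, coverage units
    weights: tuple[float, ...]
    log2_means: tuple[float, ...]
    log2_sd: float                  # tied across components
    cutoff: float | None            # coverage units; 2-component fits only
    bic_1: float
    bic_2: float
    loglik: float
    n_contigs: int
    major_minor_ratio: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "means": list(self.means),
            "sds": list(self.sds),
            "weights": list(self.weights),
            "log2_means": list(self.log2_means),
            "log2_sd": self.log2_sd,
            "cutoff": self.cutoff,
            "bic_1": self.bic_1,
            "bic_2": self.bic_2,
            "loglik": self.loglik,
            "n_contigs": self.n_contigs,
            "major_minor_ratio": self.major_minor_ratio,
        }


# ---------------------------------------------------------------------------
# weighted EM on log2 coverage, tied variance
# ---------------------------------------------------------------------------


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    cw = np.cumsum(weights[order])
    return float(values[order][np.searchsorted(cw, 0.5 * cw[-1])])


def _wstats(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    mu = float(np.average(x, weights=w))
    var = float(np.average((x - mu) ** 2, weights=w))
    return mu, var


def _loglik_1(x, w, mu, var):
    return float(np.sum(w * (-0.5 * math.log(2 * math.pi * var)
                             - (x - mu) ** 2 / (2 * var))))


def _em_2(x, w, mu0, mu1, rng, tol=1e-8, max_iter=500):
    """Tied-variance 2-component EM from the given initial means."""
    n = w.sum()
    _, var = _wstats(x, w)
    var = max(var / 4, _SD_FLOOR ** 2)
    pi = np.array([0.5, 0.5])
    mus = np.array([mu0, mu1], dtype=float)
    prev = -np.inf
    for _ in range(max_iter):
        # E step in log space
        logp = (np.log(pi)[:, None]
                - 0.5 * math.log(2 * math.pi * var)
                - (x[None, :] - mus[:, None]) ** 2 / (2 * var))
        mx = logp.max(axis=0)
        norm = mx + np.log(np.exp(logp - mx).sum(axis=0))
        ll = float(np.sum(w * norm))
        resp = np.exp(logp - norm)
        # M step (length weights fold into the responsibilities)
        wr = resp * w[None, :]
        nk = wr.sum(axis=1)
        if (nk <= 0).any():
            break
        pi = nk / n
        mus = (wr @ x) / nk
        var = float((wr * (x[None, :] - mus[:, None]) ** 2).sum() / n)
        var = max(var, _SD_FLOOR ** 2)
        if ll - prev < tol * (abs(prev) + 1):
            prev = ll
            break
        prev = ll
    order = np.argsort(mus)
    return mus[order], math.sqrt(var), pi[order], prev


def fit_mixture(hist: pd.DataFrame, seed: int = 0,
                max_cov: float = MAX_COVERAGE,
                min_cov_frac: float = 0.25,
                restarts: int = 10) -> MixtureFit:
    """Fit 1- vs 2-component mixtures to a coverage histogram, pick by BIC.

    ``hist`` needs columns ``coverage`` and ``length``; contigs with zero
    coverage, coverage above ``max_cov`` or coverage below ``min_cov_frac``
    times the weighted median are excluded from the fit (the near-zero tail
    is not part of the 1X/2X question).  Initial means come from weighted
    quantiles, jittered over ``restarts`` deterministic restarts.  With all
    coverages equal the fit degenerates to one component at the sd floor.
    """
    cov = hist["coverage"].to_numpy(dtype=float)
    lengths = hist["length"].to_numpy(dtype=float)
    keep = (cov > 0) & (cov <= max_cov)
    if keep.any() and 0 < min_cov_frac < 1:
        wmed = _weighted_median(cov[keep], lengths[keep])
        keep &= cov >= min_cov_frac * wmed
    n_excluded = int((~keep).sum())
    if n_excluded:
        log.info("excluding %d contigs outside the main coverage component "
                 "from the fit", n_excluded)
    cov, lengths = cov[keep], lengths[keep]
    n = cov.size
    if n < 20:
        raise ValueError(f"need >= 20 contigs with positive coverage, got {n}")
    x = np.log2(cov)
    w = lengths * (n / lengths.sum())  # weights sum to the contig count

    mu, var = _wstats(x, w)
    if var < _SD_FLOOR ** 2:
        log.warning("degenerate coverage histogram (all coverages equal)")
        mean = 2.0 ** mu
        return MixtureFit(1, (mean,), (mean * _LOG2 * _SD_FLOOR,), (1.0,),
                          (mu,), _SD_FLOOR, None, np.nan, np.nan,
                          _loglik_1(x, w, mu, _SD_FLOOR ** 2), n)
    ll1 = _loglik_1(x, w, mu, var)
    bic1 = -2 * ll1 + 2 * math.log(n)

    # 2-component: quantile-based starts, jittered restarts
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw /= cw[-1]

    def wquantile(q):
        return float(x[order][np.searchsorted(cw, q)])

    rng = np.random.default_rng(seed)
    sd = math.sqrt(var)
    best = None
    for r in range(restarts):
        q0, q1 = (0.25, 0.75) if r == 0 else sorted(rng.uniform(0.05, 0.95, 2))
        m0, m1 = wquantile(q0), wquantile(q1)
        if r:
            m0 += rng.normal(0, 0.1 * sd)
            m1 += rng.normal(0, 0.1 * sd)
        fit = _em_2(x, w, m0, m1, rng)
        if best is None or fit[3] > best[3]:
            best = fit
    mus2, sd2, pi2, ll2 = best
    bic2 = -2 * ll2 + 4 * math.log(n)

    separated = abs(mus2[1] - mus2[0]) > 10 * _SD_FLOOR and min(pi2) > 1e-6
    if bic2 < bic1 and separated:
        means = tuple(2.0 ** mus2)
        cutoff = _equal_density_cutoff(mus2, sd2, pi2)
        fit = MixtureFit(
            2, means,
            tuple(m * _LOG2 * sd2 for m in means),
            tuple(pi2), tuple(mus2), sd2, cutoff, bic1, bic2, ll2, n)
        fit.major_minor_ratio = peak_height_ratio(fit)
        return fit
    mean = 2.0 ** mu
    return MixtureFit(1, (mean,), (mean * _LOG2 * sd,), (1.0,),
                      (mu,), sd, None, bic1, bic2, ll1, n)


def _equal_density_cutoff(mus, sd, pi) -> float:
    """Coverage where the two weighted tied-variance densities are equal.

    With a shared variance the equal-density point is closed-form:
    ``x* = (mu0 + mu1)/2 + sd^2 * ln(pi0/pi1) / (mu1 - mu0)`` on the log2
    axis; it is clamped to the open interval between the means (midpoint
    fallback for extreme weight imbalance).
    """
    mid = 0.5 * (mus[0] + mus[1])
    xstar = mid + sd ** 2 * math.log(pi[0] / pi[1]) / (mus[1] - mus[0])
    if not mus[0] < xstar < mus[1]:
        xstar = mid
    return float(2.0 ** xstar)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def peak_height_ratio(fit: MixtureFit, hist: pd.DataFrame | None = None) -> float:
    """Ratio of the taller to the shorter fitted density peak (>= 1).

    The mixture density is evaluated on the coverage axis,
    ``f(c) = sum_j pi_j * phi(log2 c; mu_j, sd) / (c ln 2)``, and the local
    maximum on each side of the cutoff is located numerically.
    """
    if fit.n_components != 2:
        raise ValueError("peak_height_ratio requires a 2-component fit")
    mus = np.array(fit.log2_means)
    sd = fit.log2_sd
    pi = np.array(fit.weights)

    def dens(c):
        lx = np.log2(c)
        z = (lx - mus) / sd
        return float((pi * np.exp(-0.5 * z ** 2)).sum()
                     / (sd * math.sqrt(2 * math.pi) * c * _LOG2))

    cut = math.log2(fit.cutoff)
    peaks = []
    for mu_j, lo, hi in ((mus[0], mus[0] - 4 * sd, cut),
                         (mus[1], cut, mus[1] + 4 * sd)):
        res = minimize_scalar(lambda lx: -dens(2.0 ** lx),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        peaks.append(dens(2.0 ** res.x))
    taller, shorter = max(peaks), min(peaks)
    return taller / shorter if shorter > 0 else math.inf


@dataclass
class GenomeSizeEstimate:
    """Duplication-corrected genome size from the 1X/2X split."""

    assembled_bases: int
    bases_1x: int
    bases_2x: int
    estimate: int                   # bases_1x + 2 * bases_2x
    n_1x: int
    n_2x: int
    mean_cov_1x: float
    mean_cov_2x: float
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("assembled_bases", "bases_1x", "bases_2x", "estimate",
                 "n_1x", "n_2x", "mean_cov_1x", "mean_cov_2x", "flags")}


def genome_size(fit: MixtureFit, hist: pd.DataFrame) -> GenomeSizeEstimate:
    """Estimate genome size assuming the high mode is collapsed duplication.

    Contigs at or below the cutoff are 1X (assembled at true copy number);
    contigs above it are 2X (assembled once, present twice), so the genome
    size is ``bases_1x + 2 * bases_2x``.  A unimodal fit returns the
    assembled size unchanged.  A two-mode fit whose mean ratio is outside
    [1.5, 2.5] is flagged as not consistent with simple duplication.
    """
    cov = hist["coverage"].to_numpy(dtype=float)
    lengths = hist["length"].to_numpy(dtype=np.int64)
    assembled = int(lengths.sum())
    if fit.n_components == 1 or fit.cutoff is None:
        mean_cov = float(np.average(cov, weights=lengths)) if assembled else 0.0
        return GenomeSizeEstimate(assembled, assembled, 0, assembled,
                                  len(hist), 0, mean_cov, float("nan"))
    two_x = cov > fit.cutoff
    b1 = int(lengths[~two_x].sum())
    b2 = int(lengths[two_x].sum())
    flags = []
    ratio = fit.means[1] / fit.means[0]
    if not 1.5 <= ratio <= 2.5:
        flags.append(NOT_CONSISTENT)
        log.warning("mode ratio %.2f outside [1.5, 2.5]; duplication "
                    "interpretation is doubtful", ratio)
    return GenomeSizeEstimate(
        assembled, b1, b2, b1 + 2 * b2,
        int((~two_x).sum()), int(two_x.sum()),
        float(np.average(cov[~two_x], weights=lengths[~two_x])) if b1 else float("nan"),
        float(np.average(cov[two_x], weights=lengths[two_x])) if b2 else float("nan"),
        flags)


def plot_mixture(fit: MixtureFit, hist: pd.DataFrame, path) -> None:
    """Histogram with the fitted mixture density overlaid (PNG/PDF by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cov = hist["coverage"].to_numpy(dtype=float)
    cov = cov[(cov > 0)]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(cov, bins=min(100, max(10, cov.size // 20)), density=True,
            alpha=0.5, color="grey", label="contigs")
    grid = np.linspace(cov.min(), cov.max(), 500)
    mus = np.array(fit.log2_means)
    dens = np.zeros_like(grid)
    for pi_j, mu_j in zip(fit.weights, mus):
        z = (np.log2(grid) - mu_j) / fit.log2_sd
        dens += pi_j * np.exp(-0.5 * z ** 2) / (
            fit.log2_sd * math.sqrt(2 * math.pi) * grid * _LOG2)
    ax.plot(grid, dens, color="C3", label=f"{fit.n_components}-component fit")
    if fit.cutoff:
        ax.axvline(fit.cutoff, color="C0", ls="--", label="1X/2X cutoff")
    ax.set_xlabel("mean contig coverage")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
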