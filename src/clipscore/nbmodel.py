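"""Count-based CLIP normalization: NB model of CLIP CDS counts driven by
TRAP CDS counts, with dispersion estimation, one-sided tail tests, Fisher
combination across replicates, and BH FDR.

The model: background-subtracted CLIP counts for transcript i, replicate j
follow NB(mu_ij, alpha_i) with Var = mu + alpha*mu^2, where log(mu) is a
linear function of log(TRAP CDS counts) fitted per replicate, and alpha_i
is read off a mean-dispersion trend alpha(mu) = a0/mu + a1 estimated from
replicate-to-replicate variability (method of moments + iteratively
reweighted trend fit; a deliberately simple estimator without
empirical-Bayes shrinkage beyond the trend).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from clipscore.tables import AbundanceTable, TagCountTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Dispersion


@dataclass
class DispersionModel:
    """Parametric mean-dispersion trend alpha(mu) = a0/mu + a1."""

    a0: float
    a1: float
    raw: pd.Series          # per-transcript method-of-moments estimates
    mean_counts: pd.Series  # normalized per-transcript means the trend was fit against
    n_fit: int
    fallback: bool = False

    def alpha(self, mu) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        return np.maximum(0.0, self.a0 / np.maximum(mu, 1e-12) + self.a1)


def estimate_dispersion(clip_counts: pd.DataFrame,
                        size_factors: np.ndarray | None = None) -> DispersionModel:
    """Fit the mean-dispersion trend from a transcripts x replicates count matrix.

    Counts are first scaled by per-replicate size factors (median-of-ratios
    by default) so depth differences do not masquerade as dispersion. The
    per-transcript method-of-moments estimate alpha_i = (s^2 - m)/m^2 is
    regressed on 1/m via iteratively reweighted least squares with
    non-negative coefficients; the trend value at a transcript's mean is
    its final dispersion.
    """
    if clip_counts.shape[1] < 2:
        raise ValueError("dispersion estimation needs >= 2 replicates")
    mat = clip_counts.to_numpy(dtype=float)
    if size_factors is None:
        from clipscore.regulation import size_factors as mor
        try:
            size_factors = mor(np.maximum(mat, 0.0))
        except ValueError:
            totals = np.maximum(mat, 0.0).sum(axis=0)
            size_factors = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    norm = mat / np.asarray(size_factors)
    m = norm.mean(axis=1)
    s2 = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(m > 0, np.maximum(0.0, (s2 - m) / np.maximum(m, 1e-12) ** 2), np.nan)
    raw_s = pd.Series(raw, index=clip_counts.index, name="alpha_mom")
    mean_s = pd.Series(m, index=clip_counts.index, name="mean_norm")

    use = np.isfinite(raw) & (raw > 0) & (m > 0)
    if use.sum() < 50:
        med = float(np.nanmedian(raw[np.isfinite(raw) & (raw > 0)])) if (raw > 0).any() else 0.0
        logger.warning("dispersion trend fit fell back to median alpha=%.4g (%d usable transcripts)",
                       med, int(use.sum()))
        return DispersionModel(0.0, med, raw_s, mean_s, int(use.sum()), fallback=True)

    x = 1.0 / m[use]
    y = raw[use]
    design = np.column_stack([x, np.ones_like(x)])
    coef = np.array([0.0, max(float(np.median(y)), 1e-8)])
    for _ in range(20):
        fitted = np.maximum(design @ coef, 1e-10)
        w = 1.0 / fitted**2  # gamma-family variance weighting
        wd = design * np.sqrt(w)[:, None]
        wy = y * np.sqrt(w)
        new, *_ = np.linalg.lstsq(wd, wy, rcond=None)
        new = np.maximum(new, 0.0)
        if np.allclose(new, coef, rtol=1e-8, atol=1e-12):
            coef = new
            break
        coef = new
    a0, a1 = float(coef[0]), float(coef[1])
    if not (np.isfinite(a0) and np.isfinite(a1)):
        med = float(np.median(y))
        logger.warning("dispersion trend fit diverged; falling back to median alpha=%.4g", med)
        return DispersionModel(0.0, med, raw_s, mean_s, int(use.sum()), fallback=True)
    return DispersionModel(a0, a1, raw_s, mean_s, int(use.sum()))


# ---------------------------------------------------------------------------
# Count regression


@dataclass(frozen=True)
class CountRegressionFit:
    replicate_id: str
    slope: float
    intercept: float
    smear: float  # natural-scale recalibration factor
    n_fit: int


def fit_count_regression(clip_cds_counts: np.ndarray, trap_cds_counts: np.ndarray,
                         replicate: str = "", smearing: bool = True
                         ) -> tuple[np.ndarray, CountRegressionFit]:
    """Expected CLIP count mu from OLS of log(CLIP) on log(TRAP) counts.

    The fit uses transcripts with positive background-subtracted CLIP count
    and positive TRAP count; every transcript with positive TRAP count is
    assigned a mu. With ``smearing`` (default), the intercept is
    recalibrated on the natural scale so fitted means match the observed
    total over the fit set (ratio correction for the log-scale fit
    predicting the conditional median rather than the mean).

    Returns (mu vector aligned to the inputs, fit metadata); mu is NaN
    where TRAP count is non-positive.
    """
    clip = np.asarray(clip_cds_counts, dtype=float)
    trap = np.asarray(trap_cds_counts, dtype=float)
    fit_mask = (clip > 0) & (trap > 0)
    if fit_mask.sum() < 3:
        raise ValueError(f"{replicate}: count regression needs >=3 eligible transcripts")
    x = np.log(trap[fit_mask])
    y = np.log(clip[fit_mask])
    if np.ptp(x) == 0:
        raise ValueError(f"{replicate}: degenerate count regression (constant TRAP counts)")
    res = stats.linregress(x, y)
    mu = np.full(clip.shape, np.nan)
    ok = trap > 0
    mu[ok] = np.exp(res.intercept + res.slope * np.log(trap[ok]))
    smear = 1.0
    if smearing:
        smear = float(clip[fit_mask].sum() / mu[fit_mask].sum())
        mu *= smear
    return mu, CountRegressionFit(replicate, float(res.slope), float(res.intercept),
                                  smear, int(fit_mask.sum()))


# ---------------------------------------------------------------------------
# Tail test, Fisher, BH


def _nb_sf_inclusive(observed: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """P(X >= observed) under NB(mu, alpha); Poisson limit at alpha = 0."""
    observed = np.asarray(observed)
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(np.broadcast(observed, mu).shape, dtype=float)
    pois = alpha <= 0
    # survival at k-1 gives the inclusive tail P(X >= k)
    if pois.any():
        out[pois] = stats.poisson.sf(np.broadcast_to(observed, mu.shape)[pois] - 1, mu[pois])
    nb = ~pois
    if nb.any():
        n = 1.0 / alpha[nb]
        p = n / (n + mu[nb])
        out[nb] = stats.nbinom.sf(np.broadcast_to(observed, mu.shape)[nb] - 1, n, p)
    return out


def nb_pvalue(observed: int, mu: float, alpha: float) -> float:
    """One-sided upper-tail NB p-value, P(X >= observed).

    Variance is mu + alpha*mu^2; alpha = 0 uses the Poisson limit.
    p(0) = 1 exactly.
    """
    if not (np.isfinite(mu) and np.isfinite(alpha)):
        raise ValueError("mu and alpha must be finite")
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    return float(_nb_sf_inclusive(np.array(observed), np.array(mu), np.array(alpha)))


def combine_fisher(p_values) -> dict:
    """Fisher's method: chi2 = -2 sum(ln p), df = 2k.

    Zeros are clipped to the smallest positive float (logged), never dropped.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("combine_fisher needs >= 1 p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    n_zero = int((p == 0).sum())
    if n_zero:
        logger.warning("clipping %d zero p-values for Fisher combination", n_zero)
        p = np.maximum(p, np.finfo(float).tiny)
    chi2 = float(-2.0 * np.log(p).sum())
    return {"chi2": chi2, "p_combined": float(stats.chi2.sf(chi2, df=2 * p.size))}


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Pipeline


def nb_test(clip_counts: TagCountTable, abundance: AbundanceTable,
            smearing: bool = True) -> pd.DataFrame:
    """Count-based significance pipeline for one cell type.

    Background-subtracts the CLIP counts, keeps transcripts with at least
    one subtracted CLIP count across replicates, regresses log CLIP on log
    mean WT TRAP CDS counts per replicate, estimates the dispersion trend
    across replicates, computes one-sided NB p-values per replicate,
    combines them with Fisher's method, and converts to BH FDR.

    Returns a frame indexed by transcript_id with mu_<rep>, p_<rep>,
    clip_score_counts, fisher_chi2, p_combined, fdr.
    """
    sub = clip_counts.subtracted_wide()
    reps = list(sub.columns)
    trap = abundance.counts_wide(condition="wt").mean(axis=1)
    shared = sub.index.intersection(trap.index)
    sub = sub.loc[shared]
    trap = trap.loc[shared]

    eligible = (sub.to_numpy() >= 1).any(axis=1) & (trap.to_numpy() > 0)
    sub = sub.loc[eligible]
    trap_v = trap.loc[eligible].to_numpy(dtype=float)

    disp = estimate_dispersion(sub)
    alpha = disp.alpha(disp.mean_counts.loc[sub.index].to_numpy())

    out = pd.DataFrame(index=sub.index)
    resid = np.full((len(sub), len(reps)), np.nan)
    pmat = np.ones((len(sub), len(reps)))
    for k, rep in enumerate(reps):
        clip_j = sub[rep].to_numpy(dtype=float)
        mu, fit = fit_count_regression(clip_j, trap_v, replicate=rep, smearing=smearing)
        obs = np.maximum(clip_j, 0.0).astype(int)
        pmat[:, k] = _nb_sf_inclusive(obs, mu, alpha)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(clip_j > 0, np.log2(np.maximum(clip_j, 1e-300)) - np.log2(mu), np.nan)
        resid[:, k] = r
        out[f"mu_{rep}"] = mu
    for k, rep in enumerate(reps):
        out[f"p_{rep}"] = pmat[:, k]
    with np.errstate(invalid="ignore"):
        out["clip_score_counts"] = np.nanmean(resid, axis=1)
    p_clip = np.maximum(pmat, np.finfo(float).tiny)
    chi2 = -2.0 * np.log(p_clip).sum(axis=1)
    out["fisher_chi2"] = chi2
    out["p_combined"] = stats.chi2.sf(chi2, df=2 * len(reps))
    out["fdr"] = bh_fdr(out["p_combined"].to_numpy())
    out.attrs["dispersion"] = disp
    return out
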