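"""Cross-cell-type differential CLIP binding.

Transcripts must carry at least one CLIP tag in every biological replicate
of both cell types (these are the transcripts with the most accurate
scores); replicate CLIP scores are then compared between the two cell
types with an empirical-Bayes moderated two-sample t: per-transcript
pooled residual variances are shrunk toward a common prior whose scale and
degrees of freedom are estimated by moment matching on the log variances
across transcripts. A transcript is called differentially bound when its
BH-adjusted p-value is <= the cutoff AND its mean CLIP score is >= 0 in at
least one cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from clipscore.nbmodel import bh_fdr
from clipscore.tables import TagCountTable

logger = logging.getLogger(__name__)


def filter_shared_transcripts(scores_a: pd.DataFrame, scores_b: pd.DataFrame,
                              counts_a: TagCountTable, counts_b: TagCountTable) -> list:
    """Transcripts with >= 1 Cre-positive tag in every replicate of both cell types."""
    ok = None
    for counts in (counts_a, counts_b):
        wide = counts.wide("cre_pos")
        present = (wide >= 1).all(axis=1)
        present = present[present].index
        ok = set(present) if ok is None else ok & set(present)
    ok &= set(scores_a.index) & set(scores_b.index)
    return sorted(ok)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to the
    observed residual variances on the log scale."""
    pos = s2[np.isfinite(s2) & (s2 > 0)]
    if len(pos) < 2:
        return 0.0, float(np.nanmean(s2)) if np.isfinite(np.nanmean(s2)) else 0.0
    e = np.log(pos) - special.digamma(df / 2.0) + np.log(df / 2.0)
    excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


@dataclass
class ModerationInfo:
    prior_df: float
    prior_var: float
    residual_df: int


def moderated_compare(scores_a: pd.DataFrame, scores_b: pd.DataFrame,
                      adj_p_cutoff: float = 0.05, min_mean_score: float = 0.0,
                      prior_df: float | None = None) -> pd.DataFrame:
    """Moderated two-group comparison of replicate CLIP scores.

    ``scores_a``/``scores_b``: transcripts x replicates frames on a shared
    index (pre-filtered with :func:`filter_shared_transcripts`). Returns a
    frame with mean_score_a, mean_score_b, delta (a - b), t_moderated, p,
    adj_p and call in {enriched_a, enriched_b, ns}; moderation metadata in
    ``.attrs['moderation']``. ``prior_df`` overrides the estimated prior
    degrees of freedom (0 recovers the ordinary pooled t).
    """
    if not scores_a.index.equals(scores_b.index):
        raise ValueError("score tables must share an identical transcript index")
    a = scores_a.to_numpy(dtype=float)
    b = scores_b.to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each cell type needs >= 2 replicates")
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    df = na + nb - 2
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / df

    if prior_df is None:
        d0, s0_2 = _fit_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        _, s0_2 = _fit_variance_prior(s2, df)
    if not np.any(s2 > 0):
        logger.warning("zero residual variance everywhere; falling back to ordinary t")
        d0, s0_2 = 0.0, 0.0

    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_mod = s2
        df_total = df
    else:
        s2_mod = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = df + d0

    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    delta = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(se > 0, p, 1.0)
    adj = bh_fdr(p)

    expressed = np.maximum(mean_a, mean_b) >= min_mean_score
    sig = (adj <= adj_p_cutoff) & expressed
    call = np.where(sig & (delta > 0), "enriched_a",
                    np.where(sig & (delta < 0), "enriched_b", "ns"))
    out = pd.DataFrame(
        {
            "mean_score_a": mean_a, "mean_score_b": mean_b, "delta": delta,
            "t_moderated": t, "p": p, "adj_p": adj, "call": call,
        },
        index=scores_a.index,
    )
    out.attrs["moderation"] = ModerationInfo(prior_df=d0, prior_var=s0_2, residual_df=df)
    return out
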