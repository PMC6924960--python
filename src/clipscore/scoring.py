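"""Background-subtracted CLIP CDS RPKM, abundance regression, CLIP scores,
target classification, and the associated QC / length-bias controls.

The CLIP score of transcript i in replicate j is the residual of its log2
CLIP CDS RPKM from an ordinary least-squares regression of log2 CLIP RPKM
on log2 abundance (TRAP or FACS RPKM), fitted per replicate over
transcripts with at least one coding-region tag:

    score_ij = log2(CLIP_RPKM_ij) - (slope_j * log2(RPKM_i) + intercept_j)

so a score of s means 2^s-fold more CLIP signal than expected for a
transcript of that abundance. Transcripts where the background library
outnumbers the signal, or with no reads in either library, have their RPKM
set to the sentinel value 1 (log2 = 0) before scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from clipscore.annotation import Transcriptome
from clipscore.tables import AbundanceTable, TagCountTable

logger = logging.getLogger(__name__)

RPKM_SENTINEL = 1.0
TARGET_CLASSES = ("stringent", "high", "low", "non_target")


@dataclass(frozen=True)
class RegressionFit:
    """Per-replicate OLS fit of log2 CLIP RPKM on log2 abundance."""

    replicate_id: str
    slope: float
    intercept: float
    r_squared: float
    n_fit: int

    def __post_init__(self) -> None:
        if self.n_fit < 3:
            raise ValueError(f"{self.replicate_id}: regression needs >=3 transcripts, got {self.n_fit}")
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError(f"{self.replicate_id}: non-finite regression coefficients")


def compute_cds_rpkm(counts: TagCountTable, txome: Transcriptome, replicate: str) -> pd.Series:
    """Background-subtracted coding-region RPKM for one replicate.

    rpkm_i = (cre_pos_i - cre_neg_i) * 1e9
             / (cds_length_i * (total_cre_pos - total_cre_neg))

    with the sentinel rule: transcripts with cre_neg >= cre_pos, or with no
    reads in either library, get RPKM = 1.
    """
    total_pos, total_neg = counts.totals(replicate)
    if total_pos <= total_neg:
        raise ValueError(
            f"{replicate}: background library ({total_neg}) at least as deep as signal "
            f"({total_pos}); subtracted normalization undefined")
    sub = counts.for_replicate(replicate)
    tids = txome.transcript_ids
    pos = sub["cre_pos"].reindex(tids).fillna(0).to_numpy(dtype=float)
    neg = sub["cre_neg"].reindex(tids).fillna(0).to_numpy(dtype=float)
    cds_len = txome.cds_length_vector(tids)
    rpkm = (pos - neg) * 1e9 / (cds_len * (total_pos - total_neg))
    rpkm = np.where(neg >= pos, RPKM_SENTINEL, rpkm)
    return pd.Series(rpkm, index=pd.Index(tids, name="transcript_id"), name=replicate)


def fit_abundance_regression(
    clip_rpkm: pd.Series,
    abundance: AbundanceTable,
    replicate: str,
    counts: TagCountTable | None = None,
    include_sentinel: bool = True,
) -> RegressionFit:
    """OLS of log2(CLIP RPKM) on log2(abundance RPKM).

    The fit is restricted to transcripts with at least one coding-region
    Cre-positive tag in this replicate (all transcripts if ``counts`` is
    None); with ``include_sentinel=False``, transcripts whose RPKM
    collapsed to the sentinel are additionally excluded. Transcripts with
    non-positive abundance are excluded with a logged count.
    """
    rpkm = abundance.rpkm_for(clip_rpkm.index, condition="wt")
    mask = np.ones(len(clip_rpkm), dtype=bool)
    if counts is not None:
        pos = counts.for_replicate(replicate)["cre_pos"].reindex(clip_rpkm.index).fillna(0)
        mask &= pos.to_numpy() >= 1
    if not include_sentinel:
        mask &= clip_rpkm.to_numpy() != RPKM_SENTINEL
    n_zero = int((mask & (rpkm <= 0)).sum())
    if n_zero:
        logger.info("%s: excluding %d fit transcripts with non-positive abundance", replicate, n_zero)
    mask &= rpkm > 0
    mask &= clip_rpkm.to_numpy() > 0
    if mask.sum() < 3:
        raise ValueError(f"{replicate}: only {int(mask.sum())} transcripts available for the fit")
    x = np.log2(rpkm[mask])
    y = np.log2(clip_rpkm.to_numpy()[mask])
    res = stats.linregress(x, y)
    return RegressionFit(replicate, float(res.slope), float(res.intercept),
                         float(res.rvalue) ** 2, int(mask.sum()))


def compute_clip_scores(clip_rpkm: pd.Series, fit: RegressionFit,
                        abundance: AbundanceTable) -> pd.Series:
    """Residual CLIP score for every transcript, tags or not.

    Transcripts with non-positive abundance get a missing score (NaN) with
    a warning rather than an invented value.
    """
    rpkm = abundance.rpkm_for(clip_rpkm.index, condition="wt")
    score = np.full(len(clip_rpkm), np.nan)
    ok = rpkm > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: %d transcripts with non-positive abundance; score set missing",
                       fit.replicate_id, n_bad)
    score[ok] = (np.log2(clip_rpkm.to_numpy()[ok])
                 - (fit.slope * np.log2(rpkm[ok]) + fit.intercept))
    return pd.Series(score, index=clip_rpkm.index, name=fit.replicate_id)


def aggregate_and_classify(scores: pd.DataFrame, stringent_min: float = 2.0,
                           high_min: float = 1.0) -> pd.DataFrame:
    """Mean score across replicates and target class per transcript.

    stringent: score >= stringent_min in every replicate;
    high: not stringent, mean >= high_min;
    low: high_min > mean >= 0;
    non_target: mean < 0, or any replicate score missing (flagged).

    ``scores``: transcripts x replicates frame of per-replicate CLIP scores.
    """
    if scores.empty:
        raise ValueError("empty score table")
    arr = scores.to_numpy(dtype=float)
    any_missing = np.isnan(arr).any(axis=1)
    mean = np.nanmean(np.where(np.isnan(arr), np.nan, arr), axis=1)
    mean = np.where(np.isnan(arr).all(axis=1), np.nan, mean)
    stringent = (~any_missing) & (arr >= stringent_min).all(axis=1)
    high = (~stringent) & (~any_missing) & (mean >= high_min)
    low = (~stringent) & (~high) & (~any_missing) & (mean >= 0)
    cls = np.where(stringent, "stringent",
                   np.where(high, "high", np.where(low, "low", "non_target")))
    out = scores.copy()
    out.columns = [f"clip_score_{c}" for c in scores.columns]
    out["mean_clip_score"] = mean
    out["target_class"] = cls
    out["missing_replicate"] = any_missing
    return out


def score_pipeline(counts: TagCountTable, abundance: AbundanceTable, txome: Transcriptome,
                   stringent_min: float = 2.0, high_min: float = 1.0,
                   include_sentinel: bool = True) -> tuple[pd.DataFrame, dict[str, RegressionFit]]:
    """Full per-replicate scoring: RPKM -> regression -> scores -> classes.

    Returns (score table, per-replicate fits). The score table carries
    clip_rpkm_<rep>, clip_score_<rep>, mean_clip_score, target_class, and
    had_any_tag columns, indexed by transcript_id.
    """
    fits: dict[str, RegressionFit] = {}
    rpkms: dict[str, pd.Series] = {}
    scores: dict[str, pd.Series] = {}
    for rep in counts.replicates:
        rpkm = compute_cds_rpkm(counts, txome, rep)
        fit = fit_abundance_regression(rpkm, abundance, rep, counts=counts,
                                       include_sentinel=include_sentinel)
        fits[rep] = fit
        rpkms[rep] = rpkm
        scores[rep] = compute_clip_scores(rpkm, fit, abundance)
    score_frame = pd.DataFrame(scores)
    out = aggregate_and_classify(score_frame, stringent_min=stringent_min, high_min=high_min)
    for rep, r in rpkms.items():
        out[f"clip_rpkm_{rep}"] = r
    pos_wide = counts.wide("cre_pos").reindex(out.index).fillna(0)
    out["had_any_tag"] = (pos_wide > 0).any(axis=1).to_numpy()
    tid_to_gene = {t.transcript_id: t.gene_id for t in txome}
    out.insert(0, "gene_id", out.index.map(tid_to_gene))
    return out, fits


def windowed_abundance(trap_tags: pd.DataFrame, txome: Transcriptome,
                       window_nt: int = 1000, anchor: str = "start") -> AbundanceTable:
    """Abundance from reads within a terminal window of each transcript.

    Length-bias control: RPKM is recomputed using only reads whose centers
    fall within the first (anchor='start') or last (anchor='end')
    ``window_nt`` of the transcript, with denominator length
    min(window_nt, transcript length). The per-replicate total stays the
    full library size.
    """
    if window_nt < 100:
        raise ValueError("window_nt must be >= 100")
    if anchor not in ("start", "end"):
        raise ValueError(f"unknown anchor {anchor!r}")
    tags = trap_tags[trap_tags["library"] == "trap"]
    known = tags["transcript_id"].isin(set(txome.transcript_ids))
    tags = tags.loc[known].copy()
    center = (tags["start"] + tags["end"]) // 2
    length = tags["transcript_id"].map(lambda t: txome[t].length)
    if anchor == "start":
        in_window = center < np.minimum(window_nt, length)
    else:
        in_window = center >= np.maximum(0, length - window_nt)
    totals = tags.groupby("replicate_id").size()
    counted = (
        tags.loc[in_window]
        .groupby(["transcript_id", "replicate_id"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    tids = txome.transcript_ids
    rows = []
    for rep, total in totals.items():
        sub = counted[counted["replicate_id"] == rep].set_index("transcript_id")["count"]
        cnt = sub.reindex(tids).fillna(0).to_numpy(dtype=float)
        denom = np.minimum(window_nt, np.array([txome[t].length for t in tids], dtype=float))
        rpkm = cnt * 1e9 / (denom * max(int(total), 1))
        rows.append(pd.DataFrame(
            {"transcript_id": tids, "condition": "wt", "replicate": rep,
             "rpkm": rpkm, "cds_count": cnt}))
    basis = "window_1kb_5p" if anchor == "start" else "window_1kb_3p"
    return AbundanceTable(pd.concat(rows, ignore_index=True), region_basis=basis)


def replicate_correlation(counts: TagCountTable) -> pd.DataFrame:
    """Pairwise Pearson R^2 of log2(CPM + 1) between replicates (raw
    Cre-positive counts, no background subtraction)."""
    reps = counts.replicates
    if len(reps) < 2:
        raise ValueError("replicate correlation needs >= 2 replicates")
    wide = counts.wide("cre_pos")
    keep = []
    for rep in reps:
        if wide[rep].sum() <= 0:
            logger.warning("replicate %s has zero total; excluded from correlation", rep)
        else:
            keep.append(rep)
    cpm = wide[keep] * 1e6 / wide[keep].sum(axis=0)
    logged = np.log2(cpm + 1.0)
    r2 = logged.corr(method="pearson") ** 2
    return r2
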