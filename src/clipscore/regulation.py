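"""KO-vs-WT ribosome-bound abundance analysis: size factors, simplified
paired log-fold-change, class-wise CDF-shift (KS) tests, matched-control
sampling, gene-set comparisons, and the behavioral discrimination index.

The fold-change estimator here is a documented simplified stand-in for a
full count-model fit (no shrinkage): counts are scaled by median-of-ratios
size factors and the per-pair log2 ratios are averaged. Externally
computed LFC tables can be supplied anywhere an LFC vector is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def size_factors(count_matrix) -> np.ndarray:
    """Median-of-ratios per-sample scaling factors (transcripts x samples).

    factor_s = median over transcripts of count_ts / geometric-mean_t,
    over transcripts with a positive geometric mean (i.e. positive in
    every sample).
    """
    mat = np.asarray(count_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("size_factors needs a transcripts x samples matrix with >= 2 samples")
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no transcript positive in all samples; size factors undefined")
    gm = np.exp(np.log(mat[all_pos]).mean(axis=1))
    return np.median(mat[all_pos] / gm[:, None], axis=0)


def paired_lfc(ko_counts, wt_counts, factors=None, pseudocount: float = 1.0) -> np.ndarray:
    """Mean over replicate pairs of log2((ko/f + pc) / (wt/f + pc)).

    ``ko_counts``/``wt_counts``: transcripts x replicates arrays with
    matched column order (pair j = column j of each). ``factors``: length
    2k vector of size factors (ko columns then wt columns); computed by
    median-of-ratios on the concatenated matrix when omitted.
    """
    ko = np.atleast_2d(np.asarray(ko_counts, dtype=float))
    wt = np.atleast_2d(np.asarray(wt_counts, dtype=float))
    if ko.shape != wt.shape:
        raise ValueError(f"mismatched replicate pairing: ko {ko.shape} vs wt {wt.shape}")
    k = ko.shape[1]
    if factors is None:
        factors = size_factors(np.hstack([ko, wt]))
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (2 * k,):
        raise ValueError(f"expected {2 * k} size factors, got {factors.shape}")
    ko_n = ko / factors[:k]
    wt_n = wt / factors[k:]
    return np.log2(ko_n + pseudocount).mean(axis=1) - np.log2(wt_n + pseudocount).mean(axis=1)


@dataclass
class RegulationResult:
    """Per-transcript LFC joined to target classes plus class-wise KS tests."""

    table: pd.DataFrame                       # transcript_id, lfc, target_class, mean_expression
    ks: pd.DataFrame                          # class_a, class_b, ks_d, ks_p, n_a, n_b
    cdfs: dict = field(default_factory=dict)  # class -> sorted lfc values (empirical CDF support)


def cdf_shift_test(lfc, classes, min_size: int = 5,
                   reference: str = "non_target") -> RegulationResult:
    """Two-sample two-sided KS tests of the LFC distribution per target class.

    Each class is compared against the reference class and against its
    adjacent class in the ordering stringent > high > low > non_target.
    Classes below ``min_size`` are skipped with a warning.
    """
    lfc = np.asarray(lfc, dtype=float)
    classes = np.asarray(classes, dtype=object)
    order = [c for c in ("stringent", "high", "low", "non_target") if (classes == c).any()]
    groups = {c: np.sort(lfc[(classes == c) & np.isfinite(lfc)]) for c in order}

    pairs = []
    for c in order:
        if c != reference:
            pairs.append((c, reference))
    for a, b in zip(order, order[1:]):
        if (a, b) not in pairs and (b, a) not in pairs:
            pairs.append((a, b))

    rows = []
    for a, b in pairs:
        xa, xb = groups.get(a, np.array([])), groups.get(b, np.array([]))
        if len(xa) < min_size or len(xb) < min_size:
            logger.warning("skipping KS %s vs %s: group below %d members", a, b, min_size)
            continue
        res = stats.ks_2samp(xa, xb, alternative="two-sided", method="auto")
        rows.append((a, b, float(res.statistic), float(res.pvalue), len(xa), len(xb)))
    ks = pd.DataFrame(rows, columns=["class_a", "class_b", "ks_d", "ks_p", "n_a", "n_b"])
    table = pd.DataFrame({"lfc": lfc, "target_class": classes})
    return RegulationResult(table=table, ks=ks, cdfs=groups)


@dataclass
class MatchedControlSet:
    control_ids: list
    target_ids: list
    matched_on: tuple
    seed: int


def sample_matched_controls(targets, pool, txome, abundance=None,
                            match_length: bool = True, match_abundance: bool = False,
                            abundance_range: tuple = (10.0, 200.0), seed: int = 0,
                            n_bins: int = 10) -> MatchedControlSet:
    """Draw one control per target from the pool, matched on log transcript
    length and/or log abundance by decile strata.

    When abundance matching is on, both targets and pool are first
    restricted to the stated abundance range. Controls are drawn without
    replacement; an empty stratum falls back to the nearest nonempty one
    (logged). Deterministic under ``seed``.
    """
    targets = [t for t in targets if t not in set(pool)]
    pool = list(pool)
    if not targets:
        raise ValueError("no targets to match")
    if not (match_length or match_abundance):
        raise ValueError("at least one matching variable required")

    mean_rpkm = abundance.mean_rpkm("wt") if abundance is not None else None
    if match_abundance:
        if mean_rpkm is None:
            raise ValueError("abundance matching requires an abundance table")
        lo, hi = abundance_range

        def in_range(t):
            v = float(mean_rpkm.get(t, 0.0))
            return lo <= v <= hi

        targets = [t for t in targets if in_range(t)]
        pool = [t for t in pool if in_range(t)]
        if not targets:
            raise ValueError("no targets inside the abundance range")

    feats = []
    if match_length:
        feats.append(lambda t: np.log(txome[t].length))
    if match_abundance:
        feats.append(lambda t: np.log(max(float(mean_rpkm.get(t, 0.0)), 1e-12)))

    def stratum(t):
        key = []
        for f, edges in zip(feats, all_edges):
            v = f(t)
            key.append(int(np.clip(np.searchsorted(edges, v, side="right") - 1, 0, n_bins - 1)))
        return tuple(key)

    all_edges = []
    for f in feats:
        vals = np.array([f(t) for t in targets])
        qs = np.quantile(vals, np.linspace(0, 1, n_bins + 1))
        qs[0], qs[-1] = -np.inf, np.inf
        all_edges.append(qs)

    rng = np.random.default_rng(seed)
    pool_by_stratum: dict[tuple, list] = {}
    for t in pool:
        pool_by_stratum.setdefault(stratum(t), []).append(t)
    for lst in pool_by_stratum.values():
        rng.shuffle(lst)

    controls = []
    deficient = []
    strata_keys = sorted(pool_by_stratum)
    for t in sorted(targets):
        key = stratum(t)
        bucket = pool_by_stratum.get(key)
        if not bucket:
            # nearest nonempty stratum by L1 distance over bin indices
            candidates = [k for k in strata_keys if pool_by_stratum[k]]
            if not candidates:
                raise ValueError(f"pool exhausted; deficient strata: {deficient + [key]}")
            nearest = min(candidates, key=lambda k: sum(abs(a - b) for a, b in zip(k, key)))
            logger.info("stratum %s empty; drawing from nearest %s", key, nearest)
            deficient.append(key)
            bucket = pool_by_stratum[nearest]
        controls.append(bucket.pop())
    matched_on = tuple(v for v, on in (("length", match_length), ("abundance", match_abundance)) if on)
    return MatchedControlSet(control_ids=controls, target_ids=sorted(targets),
                             matched_on=matched_on, seed=seed)


def geneset_compare(values: pd.Series, geneset, background) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of a score/LFC between a gene
    set and a background set (exact enumeration for combined n <= 20 when
    tie-free, asymptotic with tie correction otherwise)."""
    if isinstance(background, MatchedControlSet):
        background = background.control_ids
    x = values.reindex(list(geneset)).dropna().to_numpy(dtype=float)
    y = values.reindex(list(background)).dropna().to_numpy(dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("both groups need >= 3 members with values")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        logger.warning("all values tied; p = 1")
        return {"wilcoxon_stat": float(len(x) * len(y) / 2.0), "p": 1.0, "n_set": len(x), "n_background": len(y)}
    small = (len(x) + len(y)) <= 20 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if small else "asymptotic")
    return {"wilcoxon_stat": float(res.statistic), "p": float(res.pvalue),
            "n_set": len(x), "n_background": len(y)}


def discrimination_index(time_displaced: float, time_unmoved: float,
                         min_total: float = 5.0) -> float:
    """Object-location memory index: (displaced - unmoved)/(displaced + unmoved).

    Animals exploring below ``min_total`` seconds in total are excluded
    (NaN). Positive values indicate preference for the displaced object.
    """
    if time_displaced < 0 or time_unmoved < 0:
        raise ValueError("exploration times must be >= 0")
    total = time_displaced + time_unmoved
    if total <= 0:
        raise ValueError("total exploration time must be positive")
    if total < min_total:
        logger.warning("total exploration %.2f s below %.2f s; excluded", total, min_total)
        return float("nan")
    return (time_displaced - time_unmoved) / total
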