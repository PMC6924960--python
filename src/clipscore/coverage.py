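"""Read-distribution summaries: genic feature distribution, per-transcript
coverage, and the weighted meta-transcript (metagene) profile.

All tags live in transcript space, so the genic feature classes are the
5'UTR, CDS and 3'UTR of each transcript model; reads on unknown
transcripts are counted as intergenic and the intron class is structurally
empty (kept in the output for completeness).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from clipscore.annotation import Transcriptome

FEATURE_CLASSES = ("utr5", "cds", "utr3", "intron", "intergenic")


def _centers(tags: pd.DataFrame) -> pd.Series:
    # read center; floor((start+end)/2) for even/odd lengths
    return (tags["start"] + tags["end"]) // 2


def genic_distribution(tags: pd.DataFrame, txome: Transcriptome) -> pd.DataFrame:
    """Assign each read to one feature class by its center and normalize
    raw counts by the total length of the class across the annotation.

    Returns a frame indexed by feature class with columns raw_count,
    raw_fraction, total_length, length_normalized_density.
    """
    known = tags["transcript_id"].isin(set(txome.transcript_ids))
    counts = dict.fromkeys(FEATURE_CLASSES, 0)
    counts["intergenic"] = int((~known).sum())
    sub = tags.loc[known]
    if not sub.empty:
        center = _centers(sub)
        cds_start = sub["transcript_id"].map(lambda t: txome[t].cds_start)
        cds_end = sub["transcript_id"].map(lambda t: txome[t].cds_end)
        in_cds = (center >= cds_start) & (center < cds_end)
        in_utr5 = center < cds_start
        counts["cds"] = int(in_cds.sum())
        counts["utr5"] = int(in_utr5.sum())
        counts["utr3"] = int((~in_cds & ~in_utr5).sum())
    lengths = {
        "utr5": sum(t.utr5_length for t in txome),
        "cds": sum(t.cds_length for t in txome),
        "utr3": sum(t.utr3_length for t in txome),
        "intron": 0,
        "intergenic": 0,
    }
    total = max(sum(counts.values()), 1)
    out = pd.DataFrame(
        {
            "raw_count": pd.Series(counts),
            "raw_fraction": pd.Series({k: v / total for k, v in counts.items()}),
            "total_length": pd.Series(lengths),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["length_normalized_density"] = np.where(
            out["total_length"] > 0, out["raw_count"] / out["total_length"], np.nan)
    out.index.name = "feature"
    return out.loc[list(FEATURE_CLASSES)]


def transcript_coverage(tags: pd.DataFrame, transcript) -> np.ndarray:
    """Per-nucleotide coverage: number of tag intervals containing each position."""
    cov = np.zeros(transcript.length, dtype=int)
    sub = tags[tags["transcript_id"] == transcript.transcript_id]
    starts = np.clip(sub["start"].to_numpy(dtype=int), 0, transcript.length)
    ends = np.clip(sub["end"].to_numpy(dtype=int), 0, transcript.length)
    np.add.at(cov, starts[starts < transcript.length], 1)
    delta = np.zeros(transcript.length + 1, dtype=int)
    np.add.at(delta, starts, 1)
    np.add.at(delta, ends, -1)
    return np.cumsum(delta[:-1])


def metagene_profile(tags: pd.DataFrame, txome: Transcriptome, top_n: int = 1000,
                     bin_nt: int = 10, anchor: str = "start_codon",
                     flank_nt: int = 1000) -> pd.DataFrame:
    """Weighted meta-transcript coverage around the start or stop codon.

    1. Rank transcripts by tag density (tags across the entire transcript /
       length) and keep the ``top_n`` densest.
    2. Keep reads whose center lies within +/- ``flank_nt`` of the anchor
       (offset 0 = first nucleotide of the start codon, or of the stop
       codon) and inside the transcript.
    3. Weight each kept read by 1/R_t, where R_t is the number of kept
       reads on its transcript, so every transcript contributes equally.
    4. Sum weights in ``bin_nt``-wide windows of center offset.
    5. Divide each bin by the fraction of the selected transcripts whose
       structure fully covers that window (representation); windows no
       transcript covers are emitted as missing.

    Returns a frame with offset_bin_start, weighted_coverage,
    representation, normalized_coverage.
    """
    if anchor not in ("start_codon", "stop_codon"):
        raise ValueError(f"unknown anchor {anchor!r}")
    known = tags[tags["transcript_id"].isin(set(txome.transcript_ids))]
    per_tx = known.groupby("transcript_id").size()
    if len(per_tx) < top_n:
        raise ValueError(f"top_n={top_n} but only {len(per_tx)} transcripts have tags")
    density = per_tx / per_tx.index.map(lambda t: txome[t].length).astype(float)
    # deterministic ranking: density desc, then transcript_id
    selected = density.sort_values(ascending=False, kind="mergesort")
    selected = selected.iloc[:top_n] if top_n else selected
    chosen = set(selected.index)

    def anchor_pos(tx) -> int:
        # stop codon: first nucleotide of the terminating codon
        return tx.cds_start if anchor == "start_codon" else tx.cds_end - 3

    sub = known[known["transcript_id"].isin(chosen)].copy()
    center = _centers(sub)
    apos = sub["transcript_id"].map(lambda t: anchor_pos(txome[t]))
    tx_len = sub["transcript_id"].map(lambda t: txome[t].length)
    offset = center - apos
    keep = (offset >= -flank_nt) & (offset < flank_nt) & (center >= 0) & (center < tx_len)
    sub = sub.loc[keep]
    offset = offset.loc[keep]

    r_t = sub.groupby("transcript_id").size()
    weights = 1.0 / sub["transcript_id"].map(r_t).to_numpy(dtype=float)

    edges = np.arange(-flank_nt, flank_nt + bin_nt, bin_nt)
    bin_idx = ((offset.to_numpy() + flank_nt) // bin_nt).astype(int)
    weighted = np.zeros(len(edges) - 1)
    np.add.at(weighted, bin_idx, weights)

    # representation: fraction of selected transcripts whose structure fully
    # covers each window [o, o + bin_nt)
    rep = np.zeros(len(edges) - 1)
    for tid in chosen:
        tx = txome[tid]
        a = anchor_pos(tx)
        lo, hi = -a, tx.length - a  # covered offset range [lo, hi)
        covers = (edges[:-1] >= lo) & (edges[1:] <= hi)
        rep += covers
    rep /= len(chosen)

    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(rep > 0, weighted / rep, np.nan)
    return pd.DataFrame(
        {
            "offset_bin_start": edges[:-1],
            "weighted_coverage": weighted,
            "representation": rep,
            "normalized_coverage": normalized,
        }
    )
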