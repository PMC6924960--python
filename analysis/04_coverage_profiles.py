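#!/usr/bin/env python
"""Read-distribution summaries on tag positions derived from the simulated
CDS counts: genic feature distribution, the weighted meta-transcript
profile around the start and stop codons, and one per-transcript coverage
track.

Writes results/genic_distribution.tsv, results/metagene_{start,stop}.tsv
and, when matplotlib can render, results/metagene.png.
"""

import pathlib
import sys

import numpy as np
import pandas as pd

from clipscore.annotation import read_annotation
from clipscore.coverage import genic_distribution, metagene_profile, transcript_coverage
from clipscore.simulate import tags_from_counts
from clipscore.tables import TagCountTable

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    txome = read_annotation(ROOT / "sim" / "txome.bed12", format="bed12")
    counts = TagCountTable.read(ROOT / "sim" / "clip_counts_a.tsv")
    # cap per-transcript counts to keep tag placement light
    df = counts.df.copy()
    df["cre_pos"] = df["cre_pos"].clip(upper=200)
    tags = tags_from_counts(txome, TagCountTable(df), read_length=35, seed=2)
    print(f"placed {len(tags)} CDS tags on {tags.transcript_id.nunique()} transcripts")

    dist = genic_distribution(tags, txome)
    dist.to_csv(ROOT / "genic_distribution.tsv", sep="\t")
    print("genic distribution (fractions):",
          dist.raw_fraction.round(3).to_dict())

    profs = {}
    for anchor in ("start_codon", "stop_codon"):
        prof = metagene_profile(tags, txome, top_n=1000, bin_nt=10,
                                anchor=anchor, flank_nt=500)
        prof.to_csv(ROOT / f"metagene_{anchor.split('_')[0]}.tsv", sep="\t", index=False)
        profs[anchor] = prof
        inside = prof.query("0 <= offset_bin_start < 300").normalized_coverage.mean()
        outside = prof.query("offset_bin_start < -100").normalized_coverage.mean()
        print(f"{anchor}: mean normalized coverage downstream {inside:.3f} "
              f"vs upstream {outside:.3f}")

    top = tags.transcript_id.value_counts().index[0]
    cov = transcript_coverage(tags, txome[top])
    print(f"densest transcript {top}: peak coverage {cov.max()}, "
          f"mean CDS coverage {cov[txome[top].cds_start:txome[top].cds_end].mean():.1f}")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 3), sharey=True)
        for ax, (anchor, prof) in zip(axes, profs.items()):
            ax.plot(prof.offset_bin_start + 5, prof.normalized_coverage, lw=1)
            ax.axvline(0, color="grey", ls="--", lw=0.8)
            ax.set_xlabel(f"offset from {anchor.replace('_', ' ')} (nt)")
        axes[0].set_ylabel("normalized weighted coverage")
        fig.tight_layout()
        fig.savefig(ROOT / "metagene.png", dpi=120)
        print(f"wrote {ROOT / 'metagene.png'}")
    except Exception as exc:  # rendering is optional
        print(f"skipping figure: {exc}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
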