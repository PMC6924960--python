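"""Count and abundance tables (thin wrappers around tidy DataFrames).

TSV on disk, UTF-8, '.' for missing, header row always present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGION_BASES = ("full_transcript", "cds", "window_1kb_5p", "window_1kb_3p")


@dataclass
class TagCountTable:
    """Per-(transcript, replicate) CDS tag counts for signal (Cre-positive)
    and background (Cre-negative) libraries.

    ``df`` columns: transcript_id, replicate, cre_pos, cre_neg. Library
    totals are the column sums per replicate.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"transcript_id", "replicate", "cre_pos", "cre_neg"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"TagCountTable missing columns: {sorted(missing)}")
        if (self.df[["cre_pos", "cre_neg"]] < 0).any().any():
            raise ValueError("negative tag counts")

    @property
    def replicates(self) -> list[str]:
        return sorted(self.df["replicate"].unique())

    def totals(self, replicate: str) -> tuple[int, int]:
        sub = self.df[self.df["replicate"] == replicate]
        return int(sub["cre_pos"].sum()), int(sub["cre_neg"].sum())

    def for_replicate(self, replicate: str) -> pd.DataFrame:
        sub = self.df[self.df["replicate"] == replicate]
        if sub.empty:
            raise KeyError(f"no counts for replicate {replicate!r}")
        return sub.set_index("transcript_id")

    def wide(self, column: str = "cre_pos") -> pd.DataFrame:
        """transcripts x replicates matrix of one count column."""
        return self.df.pivot_table(
            index="transcript_id", columns="replicate", values=column,
            aggfunc="sum", fill_value=0,
        )

    def subtracted_wide(self) -> pd.DataFrame:
        """Background-subtracted counts (cre_pos - cre_neg), may be negative."""
        return self.wide("cre_pos") - self.wide("cre_neg")

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep=".")

    @classmethod
    def read(cls, path) -> "TagCountTable":
        df = pd.read_csv(path, sep="\t", na_values=".", dtype={"transcript_id": str, "replicate": str})
        return cls(df)

    @classmethod
    def from_long_counts(cls, counts: pd.DataFrame) -> "TagCountTable":
        """Build from the long (transcript, replicate, library, count) form
        produced by :func:`clipscore.annotation.counts_from_tags`."""
        wide = counts.pivot_table(
            index=["transcript_id", "replicate"], columns="library", values="count",
            aggfunc="sum", fill_value=0,
        ).reset_index()
        for col in ("cre_pos", "cre_neg"):
            if col not in wide.columns:
                wide[col] = 0
        return cls(wide[["transcript_id", "replicate", "cre_pos", "cre_neg"]])


@dataclass
class AbundanceTable:
    """Per-(transcript, condition, replicate) abundance: RPKM plus raw CDS counts.

    ``region_basis`` records which region the RPKM denominators used
    (full transcript, CDS, or a 1-kb terminal window).
    """

    df: pd.DataFrame
    region_basis: str = "full_transcript"

    def __post_init__(self) -> None:
        required = {"transcript_id", "condition", "replicate", "rpkm"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"AbundanceTable missing columns: {sorted(missing)}")
        if self.region_basis not in REGION_BASES:
            raise ValueError(f"unknown region_basis {self.region_basis!r}")
        if not np.isfinite(self.df["rpkm"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite rpkm values")
        if "cds_count" not in self.df.columns:
            self.df = self.df.assign(cds_count=np.nan)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.df["condition"].unique())

    def mean_rpkm(self, condition: str = "wt") -> pd.Series:
        sub = self.df[self.df["condition"] == condition]
        return sub.groupby("transcript_id")["rpkm"].mean()

    def rpkm_for(self, transcript_ids, condition: str = "wt") -> np.ndarray:
        m = self.mean_rpkm(condition)
        return m.reindex(transcript_ids).fillna(0.0).to_numpy(dtype=float)

    def counts_wide(self, condition: str = "wt") -> pd.DataFrame:
        sub = self.df[self.df["condition"] == condition]
        return sub.pivot_table(
            index="transcript_id", columns="replicate", values="cds_count",
            aggfunc="sum", fill_value=0,
        )

    def write(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "region_basis", self.region_basis)
        out.to_csv(path, sep="\t", index=False, na_rep=".")

    @classmethod
    def read(cls, path) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", na_values=".",
                         dtype={"transcript_id": str, "replicate": str, "condition": str})
        basis = "full_transcript"
        if "region_basis" in df.columns:
            bases = df["region_basis"].unique()
            if len(bases) != 1:
                raise ValueError("mixed region_basis within one abundance table")
            basis = bases[0]
            df = df.drop(columns="region_basis")
        return cls(df, region_basis=basis)
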