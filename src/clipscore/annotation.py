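"""Transcript annotation, tag records, and per-gene principal-transcript selection.

Internal coordinates are transcript-space, 0-based, half-open (BED native).
GTF 1-based inclusive coordinates are converted on read; conversions happen
only at I/O boundaries.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LIBRARIES = ("cre_pos", "cre_neg", "trap")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: length, CDS interval (transcript coordinates) and gene linkage.

    ``cds_start`` is 0-based inclusive, ``cds_end`` exclusive; both lie in
    transcript coordinates, so ``cds_end - cds_start`` is the CDS length in nt.
    """

    transcript_id: str
    gene_id: str
    length: int
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            raise AnnotationError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript bounds [0, {self.length})"
            )

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def utr5_length(self) -> int:
        return self.cds_start

    @property
    def utr3_length(self) -> int:
        return self.length - self.cds_end


class Transcriptome:
    """Collection of :class:`TranscriptModel`, unique by transcript_id."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._by_id: dict[str, TranscriptModel] = {}
        for tx in transcripts:
            if tx.transcript_id in self._by_id:
                raise AnnotationError(f"duplicate transcript_id {tx.transcript_id!r}")
            self._by_id[tx.transcript_id] = tx

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._by_id.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._by_id[transcript_id]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self._by_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": [t.transcript_id for t in self],
                "gene_id": [t.gene_id for t in self],
                "length": [t.length for t in self],
                "cds_start": [t.cds_start for t in self],
                "cds_end": [t.cds_end for t in self],
                "cds_length": [t.cds_length for t in self],
            }
        )

    def cds_length_vector(self, transcript_ids: Iterable[str]) -> np.ndarray:
        return np.array([self._by_id[t].cds_length for t in transcript_ids], dtype=float)

    def write_bed12(self, path) -> None:
        """Write as transcript-space single-block BED12 (name = transcript_id|gene_id)."""
        rows = []
        for t in self:
            rows.append(
                (
                    t.transcript_id, 0, t.length, f"{t.transcript_id}|{t.gene_id}",
                    0, "+", t.cds_start, t.cds_end, "0", 1, f"{t.length},", "0,",
                )
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Annotation readers

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf(path) -> list[TranscriptModel]:
    # exons and CDS per transcript, genomic coords; CDS projected to
    # transcript coordinates through the exon chain (strand-aware).
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    strand: dict[str, str] = {}
    gene_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            feature = fields[2]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start = int(fields[3]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(fields[4])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            try:
                tid, gid = attrs["transcript_id"], attrs["gene_id"]
            except KeyError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: missing gene_id/transcript_id attribute"
                ) from exc
            gene_of[tid] = gid
            strand[tid] = fields[6]
            (exons if feature == "exon" else cds).setdefault(tid, []).append((start, end))

    out = []
    n_no_cds = 0
    for tid, ex in exons.items():
        ex = sorted(ex)
        if tid not in cds:
            n_no_cds += 1
            continue
        length = sum(e - s for s, e in ex)
        # genomic -> transcript offset of every CDS segment boundary
        offsets = np.cumsum([0] + [e - s for s, e in ex])

        def to_tx(gpos: int) -> int:
            for (s, e), off in zip(ex, offsets):
                if s <= gpos <= e:
                    return off + (gpos - s)
            raise AnnotationError(f"{tid}: CDS coordinate {gpos} outside exons")

        cs = min(s for s, _ in cds[tid])
        ce = max(e for _, e in cds[tid])
        tx_start, tx_end = to_tx(cs), to_tx(ce)
        if strand[tid] == "-":
            tx_start, tx_end = length - tx_end, length - tx_start
        out.append(TranscriptModel(tid, gene_of[tid], length, tx_start, tx_end))
    if n_no_cds:
        logger.info("dropped %d transcripts lacking a CDS", n_no_cds)
    return out


def _split_bed_name(name: str) -> tuple[str, str]:
    """BED name field -> (transcript_id, gene_id); 'tx|gene' or bare id."""
    if "|" in name:
        tid, gid = name.split("|", 1)
        return tid, gid
    return name, name


def _parse_bed12(path) -> list[TranscriptModel]:
    out = []
    n_no_cds = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise AnnotationError(f"{path}:{lineno}: expected >=8 BED12 columns")
            try:
                chrom_start, chrom_end = int(fields[1]), int(fields[2])
                thick_start, thick_end = int(fields[6]), int(fields[7])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from exc
            tid, gid = _split_bed_name(fields[3])
            if len(fields) >= 12:
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            else:
                sizes, starts = [chrom_end - chrom_start], [0]
            length = sum(sizes)
            if thick_start >= thick_end:
                n_no_cds += 1
                continue
            # project thick (CDS) boundaries through blocks into transcript space
            offsets = np.cumsum([0] + sizes)
            blocks = [
                (chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)
            ]

            def to_tx(gpos: int) -> int:
                for (s, e), off in zip(blocks, offsets):
                    if s <= gpos <= e:
                        return off + (gpos - s)
                raise AnnotationError(f"{path}:{lineno}: thick coordinate {gpos} outside blocks")

            out.append(TranscriptModel(tid, gid, length, to_tx(thick_start), to_tx(thick_end)))
    if n_no_cds:
        logger.info("dropped %d transcripts lacking a CDS", n_no_cds)
    return out


def read_annotation(path, format: str = "bed12") -> Transcriptome:
    """Read transcript annotation from GTF or BED12.

    Transcripts without a CDS are dropped (count logged). Strand-aware for
    GTF; BED12 blocks are treated as the transcript's exon chain with
    thickStart/thickEnd marking the CDS.
    """
    if format == "gtf":
        return Transcriptome(_parse_gtf(path))
    if format == "bed12":
        return Transcriptome(_parse_bed12(path))
    raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Tag records

TAG_COLUMNS = ["transcript_id", "start", "end", "replicate_id", "library"]


def read_tag_bed(path) -> pd.DataFrame:
    """Read transcript-space tag positions from 6-column BED.

    chrom = transcript_id; name = 'replicate:library' (library one of
    cre_pos / cre_neg / trap).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["transcript_id", "start", "end", "name", "score", "strand"],
        dtype={"transcript_id": str, "name": str},
    )
    rep_lib = df["name"].str.split(":", n=1, expand=True)
    if rep_lib.shape[1] < 2 or rep_lib[1].isna().any():
        raise AnnotationError(f"{path}: tag name field must be 'replicate:library'")
    out = df[["transcript_id", "start", "end"]].copy()
    out["replicate_id"] = rep_lib[0]
    out["library"] = rep_lib[1]
    bad = ~out["library"].isin(LIBRARIES)
    if bad.any():
        raise AnnotationError(f"{path}: unknown library labels {sorted(out.loc[bad, 'library'].unique())}")
    return out


def write_tag_bed(tags: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": tags["transcript_id"],
            "start": tags["start"],
            "end": tags["end"],
            "name": tags["replicate_id"].astype(str) + ":" + tags["library"].astype(str),
            "score": 0,
            "strand": "+",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def counts_from_tags(tags: pd.DataFrame, txome: Transcriptome, region: str = "cds") -> pd.DataFrame:
    """Count tags per (transcript, replicate, library) over the CDS or full transcript.

    A tag counts toward the CDS if its interval overlaps [cds_start, cds_end)
    by at least 1 nt. Unknown transcript_ids are skipped with a warning.
    Returns a long table: transcript_id, replicate, library, count.
    """
    if region not in ("cds", "full"):
        raise ValueError(f"unknown region {region!r}")
    known = tags["transcript_id"].isin(set(txome.transcript_ids))
    n_skip = int((~known).sum())
    if n_skip:
        logger.warning("skipping %d tags on unknown transcripts", n_skip)
    tags = tags.loc[known]
    if region == "cds":
        cds_start = tags["transcript_id"].map(lambda t: txome[t].cds_start)
        cds_end = tags["transcript_id"].map(lambda t: txome[t].cds_end)
        tags = tags.loc[(tags["end"] > cds_start) & (tags["start"] < cds_end)]
    counts = (
        tags.groupby(["transcript_id", "replicate_id", "library"], observed=True)
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"replicate_id": "replicate"})
    )
    return counts


# ---------------------------------------------------------------------------
# Principal-transcript selection


def select_principal_transcripts(
    txome: Transcriptome, abundance, min_rpkm: float = 1.0
) -> Transcriptome:
    """Keep a single transcript per gene: the one with highest mean RPKM
    across WT replicates, then filter for mean RPKM >= ``min_rpkm``.

    Ties are broken lexicographically by transcript_id. Genes whose every
    transcript falls below the filter are dropped.
    """
    df = abundance.df if hasattr(abundance, "df") else abundance
    wt = df[df["condition"] == "wt"] if "condition" in df.columns else df
    mean_rpkm = wt.groupby("transcript_id")["rpkm"].mean()

    best: dict[str, TranscriptModel] = {}
    best_rpkm: dict[str, float] = {}
    for tx in txome:
        r = float(mean_rpkm.get(tx.transcript_id, 0.0))
        g = tx.gene_id
        incumbent = best.get(g)
        if (
            incumbent is None
            or r > best_rpkm[g]
            or (r == best_rpkm[g] and tx.transcript_id < incumbent.transcript_id)
        ):
            best[g], best_rpkm[g] = tx, r
    kept = [tx for g, tx in best.items() if best_rpkm[g] >= min_rpkm]
    return Transcriptome(sorted(kept, key=lambda t: t.transcript_id))
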