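"""Synthetic CLIP/TRAP experiment generator with known ground truth.

Emulates the statistical structure of a cell-type-specific CLIP experiment:

* a transcriptome with log-normal transcript lengths and beta-distributed
  CDS fractions;
* log-normal ribosome-bound (TRAP) transcript abundance, measured per
  replicate as NB-sampled counts and RPKM;
* CLIP CDS tag counts per replicate drawn from a negative binomial whose
  mean follows a power law in abundance, scaled by CDS length, a
  per-replicate library-size factor, and a multiplicative binding
  enrichment (2^binding_factor_log2) for a minority of true targets;
* a nonspecific Cre-negative background library whose mean is a fixed
  fraction of the binding-free signal mean;
* KO abundance down-regulated in proportion to binding enrichment;
* optionally a second cell type with partially overlapping targets.

A single integer seed determines every output byte; per-stage RNG streams
are derived from it with stable spawn keys so partial re-runs reproduce.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from clipscore.annotation import TranscriptModel, Transcriptome
from clipscore.tables import AbundanceTable, TagCountTable

_STAGES = {
    "txome": 0,
    "targets": 1,
    "abundance_true": 2,
    "size_factors": 3,
    "trap_counts": 4,
    "clip_a": 5,
    "clip_b": 6,
    "ko": 7,
    "tag_positions": 8,
    "trap_counts_b": 9,
    "uniform": 10,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES[stage],)))


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB draw with mean mu and variance mu + alpha*mu^2 (Poisson at alpha=0)."""
    mu = np.asarray(mu, dtype=float)
    if alpha == 0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions.

    Lengths/abundances are log-normal with natural-log parameters; binding
    enrichment is normal on the log2 scale; CLIP counts NB with dispersion
    ``dispersion_alpha`` (TRAP counts use the much smaller
    ``trap_dispersion_alpha``, reflecting deep, well-correlated RNA-seq
    replicates versus noisy CLIP libraries).
    """

    n_genes: int = 8000
    n_replicates: int = 3
    seed: int = 0
    length_log_mean: float = 7.8       # ln nt; median ~2.4 kb
    length_log_sd: float = 0.7
    cds_fraction_mean: float = 0.45
    trap_log_mean: float = 1.5         # ln RPKM; median ~4.5
    trap_log_sd: float = 1.2
    depth_clip: int = 1_000_000        # unique CLIP tags per replicate
    depth_trap: int = 20_000_000       # TRAP reads per replicate
    slope_b: float = 1.0               # power-law link, CLIP mean ~ abundance^b
    dispersion_alpha: float = 0.05
    trap_dispersion_alpha: float = 0.005
    background_fraction: float = 0.10
    target_fraction: float = 0.05
    binding_factor_log2_mean: float = 2.0
    binding_factor_log2_sd: float = 0.8
    binding_factor_log2_min: float = 0.25  # truncation: targets are enriched by construction
    ko_coupling_gamma: float = 0.15    # KO log2 down-regulation per unit binding enrichment
    ko_noise_sd: float = 0.05
    shared_target_fraction: float = 0.5
    second_cell_type: bool = False
    library_size_log_sd: float = 0.15  # replicate depth variation (log-normal)

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be >= 1")
        for name in ("target_fraction", "cds_fraction_mean", "shared_target_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction outside [0, 1)")
        if self.dispersion_alpha < 0 or self.trap_dispersion_alpha < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth_clip <= 0 or self.depth_trap <= 0:
            raise ValueError("library depths must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    ``df`` columns: transcript_id, is_target, binding_factor_log2,
    true_ko_lfc, cell_types (comma-joined membership, empty for
    non-targets), binding_factor_log2_b (second cell type).
    """

    df: pd.DataFrame
    clip_size_factors: dict
    config: SimConfig

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep=".")


@dataclass
class SimData:
    txome: Transcriptome
    abundance: AbundanceTable
    clip: TagCountTable
    truth: SimTruth
    clip_b: TagCountTable | None = None
    abundance_b: AbundanceTable | None = None


def _simulate_transcriptome(cfg: SimConfig) -> Transcriptome:
    rng = _rng(cfg.seed, "txome")
    n = cfg.n_genes
    lengths = np.maximum(200, rng.lognormal(cfg.length_log_mean, cfg.length_log_sd, n)).astype(int)
    # beta around cds_fraction_mean with concentration 10
    a = 10.0 * cfg.cds_fraction_mean
    b = 10.0 * (1.0 - cfg.cds_fraction_mean)
    frac = rng.beta(a, b, n)
    cds_len = np.maximum(60, (frac * lengths).astype(int))
    cds_len = np.minimum(cds_len, lengths - 20)  # leave room for UTRs
    utr_split = rng.beta(2.0, 3.0, n)  # 5'UTRs shorter than 3'UTRs on average
    cds_start = ((lengths - cds_len) * utr_split).astype(int)
    width = len(str(n))
    txs = [
        TranscriptModel(f"t{i:0{width}d}", f"g{i:0{width}d}", int(lengths[i]),
                        int(cds_start[i]), int(cds_start[i] + cds_len[i]))
        for i in range(n)
    ]
    return Transcriptome(txs)


def _assign_targets(cfg: SimConfig, transcript_ids: list[str]) -> pd.DataFrame:
    rng = _rng(cfg.seed, "targets")
    n = len(transcript_ids)
    n_targets = int(round(cfg.target_fraction * n))
    idx = rng.choice(n, size=n_targets, replace=False)
    bf = np.zeros(n)
    bf_b = np.zeros(n)
    draws = np.maximum(
        cfg.binding_factor_log2_min,
        rng.normal(cfg.binding_factor_log2_mean, cfg.binding_factor_log2_sd, n_targets),
    )
    cell = np.array([""] * n, dtype=object)
    if cfg.second_cell_type and n_targets:
        n_shared = int(round(cfg.shared_target_fraction * n_targets))
        n_a_only = (n_targets - n_shared + 1) // 2
        order = rng.permutation(n_targets)
        shared, rest = order[:n_shared], order[n_shared:]
        a_only, b_only = rest[:n_a_only], rest[n_a_only:]
        bf[idx[shared]] = draws[shared]
        bf_b[idx[shared]] = draws[shared]
        bf[idx[a_only]] = draws[a_only]
        bf_b[idx[b_only]] = draws[b_only]
        cell[idx[shared]] = "A,B"
        cell[idx[a_only]] = "A"
        cell[idx[b_only]] = "B"
    else:
        bf[idx] = draws
        cell[idx] = "A"
    is_target = np.zeros(n, dtype=bool)
    is_target[idx] = True
    return pd.DataFrame(
        {
            "transcript_id": transcript_ids,
            "is_target": is_target,
            "binding_factor_log2": bf,
            "binding_factor_log2_b": bf_b,
            "cell_types": cell,
        }
    )


def _simulate_clip(cfg: SimConfig, rng: np.random.Generator, rpkm_true: np.ndarray,
                   cds_len: np.ndarray, bf: np.ndarray) -> tuple[pd.DataFrame, dict]:
    """NB CLIP counts for one cell type; returns long count table + size factors."""
    rate = rpkm_true ** cfg.slope_b * (cds_len / 1e3)
    rate_signal = rate * np.exp2(bf)
    norm = rate_signal.sum()
    s = rng.lognormal(0.0, cfg.library_size_log_sd, cfg.n_replicates)
    frames = []
    size_factors = {}
    n = len(rate)
    width = len(str(n))
    tids = [f"t{i:0{width}d}" for i in range(n)]
    for j in range(cfg.n_replicates):
        rep = f"rep{j + 1}"
        mu_pos = s[j] * cfg.depth_clip * rate_signal / norm
        mu_neg = cfg.background_fraction * s[j] * cfg.depth_clip * rate / norm
        pos = _nb_sample(rng, mu_pos, cfg.dispersion_alpha)
        neg = _nb_sample(rng, mu_neg, cfg.dispersion_alpha)
        frames.append(pd.DataFrame(
            {"transcript_id": tids, "replicate": rep, "cre_pos": pos, "cre_neg": neg}))
        size_factors[rep] = float(s[j])
    return pd.concat(frames, ignore_index=True), size_factors


def _simulate_trap(cfg: SimConfig, rng: np.random.Generator, rpkm_true: np.ndarray,
                   lengths: np.ndarray, cds_len: np.ndarray,
                   lfc: np.ndarray) -> AbundanceTable:
    """WT and KO TRAP abundance: NB full-transcript counts, binomially
    thinned to CDS counts, RPKM from the sampled counts.

    The KO mean uses the WT normalization constant so the configured
    KO/WT mean ratio equals 2^true_ko_lfc exactly per transcript.
    """
    n = len(rpkm_true)
    width = len(str(n))
    tids = [f"t{i:0{width}d}" for i in range(n)]
    rate_wt = rpkm_true * lengths
    norm = rate_wt.sum()
    frames = []
    for cond in ("wt", "ko"):
        mult = np.exp2(lfc) if cond == "ko" else 1.0
        for j in range(cfg.n_replicates):
            s = rng.lognormal(0.0, cfg.library_size_log_sd)
            mu = s * cfg.depth_trap * rate_wt * mult / norm
            full = _nb_sample(rng, mu, cfg.trap_dispersion_alpha)
            cds = rng.binomial(full, cds_len / lengths)
            total = full.sum()
            rpkm = full * 1e9 / (lengths * max(total, 1))
            frames.append(pd.DataFrame(
                {
                    "transcript_id": tids, "condition": cond, "replicate": f"rep{j + 1}",
                    "rpkm": rpkm, "cds_count": cds, "full_count": full,
                }))
    return AbundanceTable(pd.concat(frames, ignore_index=True), region_basis="full_transcript")


def simulate_experiment(config: SimConfig) -> SimData:
    """Run the full generator; byte-identical outputs for a fixed config."""
    config.validate()
    txome = _simulate_transcriptome(config)
    tids = txome.transcript_ids
    lengths = np.array([txome[t].length for t in tids], dtype=float)
    cds_len = txome.cds_length_vector(tids)

    truth_df = _assign_targets(config, tids)
    bf = truth_df["binding_factor_log2"].to_numpy()
    bf_b = truth_df["binding_factor_log2_b"].to_numpy()

    rpkm_true = _rng(config.seed, "abundance_true").lognormal(
        config.trap_log_mean, config.trap_log_sd, config.n_genes)

    ko_rng = _rng(config.seed, "ko")
    true_lfc = -config.ko_coupling_gamma * bf + ko_rng.normal(0.0, config.ko_noise_sd, config.n_genes)
    truth_df = truth_df.assign(true_ko_lfc=true_lfc, rpkm_true=rpkm_true)

    abundance = _simulate_trap(config, _rng(config.seed, "trap_counts"),
                               rpkm_true, lengths, cds_len, true_lfc)

    clip_df, sf_a = _simulate_clip(config, _rng(config.seed, "clip_a"), rpkm_true, cds_len, bf)
    clip = TagCountTable(clip_df)

    clip_b = abundance_b = None
    if config.second_cell_type:
        clip_b_df, sf_b = _simulate_clip(config, _rng(config.seed, "clip_b"),
                                         rpkm_true, cds_len, bf_b)
        clip_b = TagCountTable(clip_b_df)
        zero_lfc = np.zeros(config.n_genes)
        abundance_b = _simulate_trap(config, _rng(config.seed, "trap_counts_b"),
                                     rpkm_true, lengths, cds_len, zero_lfc)
        size_factors = {"A": sf_a, "B": sf_b}
    else:
        size_factors = {"A": sf_a}

    truth = SimTruth(df=truth_df, clip_size_factors=size_factors, config=config)
    return SimData(txome=txome, abundance=abundance, clip=clip, truth=truth,
                   clip_b=clip_b, abundance_b=abundance_b)


def expected_clip_mean(config: SimConfig, truth: SimTruth, txome: Transcriptome,
                       replicate: str, cell_type: str = "A") -> np.ndarray:
    """Configured NB mean of the Cre-positive CLIP counts (for tests)."""
    tids = txome.transcript_ids
    cds_len = txome.cds_length_vector(tids)
    rpkm_true = truth.df.set_index("transcript_id")["rpkm_true"].reindex(tids).to_numpy()
    col = "binding_factor_log2" if cell_type == "A" else "binding_factor_log2_b"
    bf = truth.df.set_index("transcript_id")[col].reindex(tids).to_numpy()
    rate = rpkm_true ** config.slope_b * (cds_len / 1e3)
    norm = (rate * np.exp2(bf)).sum()
    s = truth.clip_size_factors[cell_type][replicate]
    return s * config.depth_clip * rate * np.exp2(bf) / norm


def simulate_uniform_coverage(txome: Transcriptome, reads_per_transcript: int,
                              read_length: int, seed: int) -> pd.DataFrame:
    """Uniform-coverage tag positions: fixture for metagene flatness checks.

    Read starts are uniform on [0, length - read_length]; each transcript
    receives exactly ``reads_per_transcript`` reads. Transcripts shorter
    than ``read_length`` are skipped with a warning.
    """
    import logging

    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES["uniform"],)))
    rows = []
    for tx in txome:
        if read_length >= tx.length:
            logging.getLogger(__name__).warning(
                "skipping %s: read_length %d >= transcript length %d",
                tx.transcript_id, read_length, tx.length)
            continue
        starts = rng.integers(0, tx.length - read_length + 1, size=reads_per_transcript)
        for s in np.sort(starts):
            rows.append((tx.transcript_id, int(s), int(s) + read_length, "rep1", "cre_pos"))
    return pd.DataFrame(rows, columns=["transcript_id", "start", "end", "replicate_id", "library"])


def tags_from_counts(txome: Transcriptome, counts: TagCountTable, read_length: int,
                     seed: int) -> pd.DataFrame:
    """Place each counted Cre-positive CDS tag uniformly within its CDS.

    Positional plumbing for coverage analyses on simulated counts; no
    sequence-level structure is modelled.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES["tag_positions"],)))
    rows = []
    for row in counts.df.itertuples(index=False):
        tx = txome[row.transcript_id]
        lo = max(0, tx.cds_start - read_length + 1)
        hi = max(lo + 1, min(tx.cds_end - 1, tx.length - read_length) + 1)
        starts = rng.integers(lo, hi, size=int(row.cre_pos))
        for s in starts:
            rows.append((tx.transcript_id, int(s), int(s) + read_length, row.replicate, "cre_pos"))
    return pd.DataFrame(rows, columns=["transcript_id", "start", "end", "replicate_id", "library"])
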