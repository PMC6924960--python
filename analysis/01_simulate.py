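#!/usr/bin/env python
"""Generate the synthetic two-cell-type CLIP/TRAP experiment used by the
downstream analysis steps.

Writes the transcript annotation, CLIP CDS tag counts (both cell types),
TRAP abundance (WT + KO), and the generator ground truth to results/sim/.
Everything downstream (02-06) reads these files, exercising the same TSV/BED
interfaces an external dataset would use.
"""

import pathlib
import sys

from clipscore.simulate import SimConfig, simulate_experiment

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=1, second_cell_type=True)
    sim = simulate_experiment(cfg)

    sim.txome.write_bed12(OUT / "txome.bed12")
    sim.clip.write(OUT / "clip_counts_a.tsv")
    sim.clip_b.write(OUT / "clip_counts_b.tsv")
    sim.abundance.write(OUT / "trap_a.tsv")
    sim.abundance_b.write(OUT / "trap_b.tsv")
    sim.truth.write(OUT / "truth.tsv")
    cfg.to_yaml(OUT / "config.yaml")

    truth = sim.truth.df
    print(f"simulated {cfg.n_genes} genes, {cfg.n_replicates} replicates/cell type")
    print(f"planted targets: {int(truth.is_target.sum())} "
          f"(A-only {(truth.cell_types == 'A').sum()}, "
          f"B-only {(truth.cell_types == 'B').sum()}, "
          f"shared {(truth.cell_types == 'A,B').sum()})")
    print(f"wrote {len(list(OUT.iterdir()))} files to {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
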