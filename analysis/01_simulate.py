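"""Simulate the study's observables with known ground truth.

Two synthetic datasets are produced under results/sim/:

* ``sx/`` — a 35-line single-time-point lineage (4 haplotypes over 25
  SNPs, progenitor haploid copy number 190) with the real treatment
  design (9 control, 9 Ni80, 8 Cu40, 9 Ni80Cu40), sampled at generation
  110: per-sample depth tables, pooled allele counts, metadata, truth.
* ``ch_controls/`` — diploid 28S copy-number trajectories of 14 control
  lines snapshotted at generations 83, 159 and 188, for the
  interval-length analysis.

Run: python analysis/01_simulate.py  (seed fixed at 1)
"""

from pathlib import Path

import pandas as pd

from rdnavar.io_formats import write_depth_table, write_metadata, write_table
from rdnavar.pipeline import RunConfig
from rdnavar.simulate import (SimConfig, derive_seed, simulate_cn_trajectories,
                              simulate_dataset, write_truth)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    treatments = (["control"] * 9 + ["Ni80"] * 9 + ["Cu40"] * 8
                  + ["Ni80Cu40"] * 9)
    cfg = SimConfig(generations=110, seed=derive_seed(SEED, "sx"))
    data = simulate_dataset(cfg, n_lines=35, seed=derive_seed(SEED, "sx"),
                            sampling_generation=110, lineage="SX",
                            treatments=treatments)
    sx = OUT / "sx"
    (sx / "depth").mkdir(parents=True, exist_ok=True)
    for sample_id, profiles in data["depth_profiles"].items():
        write_depth_table(profiles.values(), sx / "depth" / f"{sample_id}.depth.tsv")
    write_table(data["allele_counts"], sx / "allele_counts.tsv")
    write_metadata(data["metadata"], sx / "metadata.tsv")
    write_truth(data["states"], data["H"], data["P_true"], sx / "truth")
    print(f"SX-like dataset: 35 samples, {cfg.n_snps} SNP sites, "
          f"progenitor diploid copy number {2 * cfg.progenitor_haploid_cn}")

    gens = [83, 159, 188]
    snaps = simulate_cn_trajectories(14, 188, cfg, seed=derive_seed(SEED, "ch"),
                                     snapshot_generations=gens)
    rows = [{"line_id": f"CH{line + 1:03d}", "generation": g,
             "diploid_cn": int(snaps[line, j])}
            for line in range(14) for j, g in enumerate(gens)]
    ch = OUT / "ch_controls"
    ch.mkdir(parents=True, exist_ok=True)
    write_table(pd.DataFrame(rows), ch / "cn_by_generation.tsv")
    print(f"CH-control-like trajectories: 14 lines x {len(gens)} samplings "
          f"(generations {gens}); copy-number range "
          f"{snaps.min()}-{snaps.max()}")


if __name__ == "__main__":
    main()
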