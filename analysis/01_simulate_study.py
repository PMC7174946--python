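#!/usr/bin/env python
"""Generate the synthetic five-arm study all later steps analyze.

Emits the design table, four RNA count matrices, the per-animal
phenotype table at the published operating point, and the planted-truth
sidecar, all under results/study/.
"""

import sys

from cernapipe import io, synthetic

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main():
    out = io.ensure_dir("results/study")
    design = synthetic.generate_design(5, seed=SEED)
    design.to_csv(out / "design.csv", index=False)

    config = synthetic.SimulationConfig()
    matrices, truth = synthetic.generate_multiomics(design, config, seed=SEED)
    for category, counts in matrices.items():
        io.write_counts(counts, out / f"counts_{category}.tsv")
    truth.to_json(out / "truth.json")

    phen = synthetic.generate_phenotypes(design, seed=SEED)
    phen.to_csv(out / "phenotypes.csv", index=False)

    n_de = len(truth.de_features["DM vs NC"])
    print(f"simulated {len(design)} animals across {design['group'].nunique()} groups (seed {SEED})")
    for category, counts in matrices.items():
        print(f"  {category}: {counts.shape[0]} features x {counts.shape[1]} samples")
    print(f"  planted DM-vs-NC differential features: {n_de}")
    print(f"  planted efficacy features per arm: "
          + ", ".join(f"{t}={len(s)}" for t, s in truth.efficacy_features.items()))
    print(f"wrote inputs to {out}")


if __name__ == "__main__":
    main()
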