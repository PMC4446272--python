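"""Generate the synthetic two-diet, two-timepoint study.

Writes the raw study (expression, samples, physiology, gene-set and
regulon GMTs, truth manifest) under scratch/study/ and prints what was
planted.  Downstream analysis scripts read from that directory.
"""

import argparse
from pathlib import Path

import trilayer as tl


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("scratch/study"))
    args = ap.parse_args()

    study = tl.generate_study(tl.SynthConfig(seed=args.seed))
    paths = tl.write_study(study, args.out)

    n_genes, n_samples = study.expression.shape
    print(f"study written to {args.out}")
    print(f"  {n_genes} genes x {n_samples} samples "
          f"({dict(study.samples.groupby(['timepoint', 'diet']).size())})")
    print(f"  {len(study.processes)} process sets, {len(study.regulons)} regulons")
    print(f"  planted regulons: {study.truth.planted_regulons}")
    print(f"  planted processes: {list(study.truth.planted_processes)}")
    print(f"  phenotype-linked parameters: "
          f"{ {k: len(v) for k, v in study.truth.linked_params.items()} }")
    print(f"  {len(study.truth.de_direction)} genes truly differentially expressed")


if __name__ == "__main__":
    main()
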