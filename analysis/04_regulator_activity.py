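"""Transcription-factor regulon enrichment and activation scoring.

Hypergeometric over-representation of each regulon among the DE genes,
activation z from the DE targets' fold-change signs, and clustering of
TFs with identical DE target sets.  Writes
results/<timepoint>/regulators.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import trilayer as tl
from trilayer.pipeline import write_regulator_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=Path("scratch/study"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    study = tl.read_study(args.study)
    for tp_dir in sorted(args.results.iterdir()):
        de_path = tp_dir / "de.tsv"
        if not de_path.exists():
            continue
        de = pd.read_csv(de_path, sep="\t", index_col=0)
        recs = tl.cluster_regulators(tl.regulon_enrichment(de, study.regulons))
        write_regulator_table(recs, tp_dir / "regulators.tsv")
        sig = recs[recs["significant"]]
        print(f"{tp_dir.name}: {len(sig)}/{len(recs)} TFs significant, "
              f"{recs['cluster'].nunique()} clusters")
        indexed = recs.set_index("tf")
        for tf, direction in study.truth.planted_regulons.items():
            row = indexed.loc[tf]
            ok = row["significant"] and np.sign(row["z"]) == direction
            print(f"   planted {tf} (dir {direction:+d}): p={row['p_value']:.3g} "
                  f"z={row['z']:+.2f} -> {'recovered' if ok else 'MISSED'}")


if __name__ == "__main__":
    main()
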