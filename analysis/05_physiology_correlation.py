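"""Spearman correlation of physiological parameters with expression.

Per timepoint, correlates every parameter against every gene across the
animals of both diet groups and keeps genes with |rho| > 0.8 and
p < 0.05.  Writes results/<timepoint>/physiology_correlations.tsv.
"""

import argparse
from pathlib import Path

import trilayer as tl


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=Path("scratch/study"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    study = tl.read_study(args.study)
    em_all = tl.ExpressionMatrix(study.expression, study.samples)
    for tp in em_all.timepoints():
        physio = study.physiology
        physio = physio[physio["timepoint"] == tp].drop(columns="timepoint")
        corr = tl.correlate_parameters(em_all.subset(tp), physio)
        out = args.results / tp
        out.mkdir(parents=True, exist_ok=True)
        corr.to_csv(out / "physiology_correlations.tsv", sep="\t", index=False)
        linked = corr.groupby("parameter").size().to_dict()
        print(f"{tp}: {len(linked)} linked parameters {linked}")
        for param, module in study.truth.linked_params.items():
            found = set(corr[corr["parameter"] == param]["gene"])
            rate = len(found & set(module)) / len(module)
            print(f"   planted {param}: {rate:.0%} of its {len(module)}-gene "
                  f"module recovered")


if __name__ == "__main__":
    main()
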