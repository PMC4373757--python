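"""Paired differential expression at each post-surgery timepoint.

Reads the experiment written by 01_simulate_experiment.py, runs the
per-probe paired t-test (ipsilateral vs contralateral limb within animal),
BH adjustment and probe-to-gene collapsing, then classifies significant
genes by volcano fold-change thresholds (FC > 2.8 / < 0.35 at 2 weeks,
1.5 / 0.5 later).  Writes per-timepoint DE tables and gene lists, and
reports how well the recovered genes match the planted truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from ptoa.de import paired_de, volcano_classify
from ptoa.io import read_experiment, read_tsv, write_gene_set, write_tsv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    exp = read_experiment(args.out_dir / "experiment")
    truth_path = args.out_dir / "experiment" / "truth.tsv"
    truth = read_tsv(truth_path) if truth_path.exists() else None

    up = {"2w": 2.8, "4w": 1.5, "8w": 1.5}
    down = {"2w": 0.35, "4w": 0.5, "8w": 0.5}
    for tp in dict.fromkeys(exp.samples["timepoint"]):
        res = paired_de(exp, tp, alpha=args.alpha)
        table = res.genes.reset_index()
        table["volcano"] = volcano_classify(res, up_fc=up.get(tp, 2.0),
                                            down_fc=down.get(tp, 0.5)).values
        write_tsv(table, args.out_dir / f"de_{tp}.tsv", stage="de")
        sig = res.significant_genes
        line = f"{tp}: {len(sig)} significant genes ({res.n_pairs} pairs)"
        if truth is not None:
            tru = set(truth[(truth["timepoint"] == tp) & truth["is_de"]]["gene"])
            tp_rec = len(tru & sig) / len(tru) if tru else float("nan")
            fp = len(sig - tru)
            line += f"; planted {len(tru)}, recovered {tp_rec:.1%}, false positives {fp}"
        print(line)
        if sig:
            write_gene_set(res.gene_set(f"this_study_{tp}"),
                           args.out_dir / f"genelist_{tp}.tsv", stage="de")


if __name__ == "__main__":
    main()
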