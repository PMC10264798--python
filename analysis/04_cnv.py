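#!/usr/bin/env python
"""Curate the CNV export: classify phenotype text, deduplicate on exact
coordinates + dosage, and summarize by dosage and phenotype group.

    python analysis/04_cnv.py --exports results/simulated --out results/catalog
"""

import argparse
import csv
from pathlib import Path

from ctcf_catalog.cnv import summarize_cnvs
from ctcf_catalog.pipeline import curate_cnv_rows
from ctcf_catalog.report import cnv_frame


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--exports", type=Path, default=Path("results/simulated"))
    parser.add_argument("--out", type=Path, default=Path("results/catalog"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    with open(args.exports / "cnv_export.tsv") as fh:
        rows = [
            {**row, "start": int(row["start"]), "end": int(row["end"])}
            for row in csv.DictReader(fh, delimiter="\t")
        ]
    distinct, stats = curate_cnv_rows(rows)
    cnv_frame(distinct).to_csv(args.out / "cnv_catalog.tsv", sep="\t", index=False)
    summary = summarize_cnvs(distinct)
    summary.to_csv(args.out / "cnv_summary.tsv", sep="\t", index=False)

    gains = sum(r.dosage == "gain" for r in distinct)
    print(
        f"{stats['n_records']} CNV records -> {stats['n_distinct']} distinct "
        f"({stats['n_duplicates']} duplicates removed); "
        f"{gains} gains / {stats['n_distinct'] - gains} losses"
    )
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
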