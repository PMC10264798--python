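#!/usr/bin/env python
"""Print the headline numbers of a finished run: filter-step counts, NDD
share, consequence-class and phenotype proportions.

    python analysis/05_report.py --catalog results/catalog
"""

import argparse
import json
from pathlib import Path

import pandas as pd


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--catalog", type=Path, default=Path("results/catalog"))
    args = parser.parse_args()

    manifest = json.loads((args.catalog / "run_manifest.json").read_text())
    fc = manifest["filter_counts"]
    ds = manifest["dedup_stats"]
    print("pipeline counts:")
    print(
        f"  {ds['n_records']} records ingested -> {ds['n_distinct']} distinct "
        f"({ds['n_duplicate_records']} duplicate records)"
    )
    print(
        f"  {fc['exonic']} exonic; {fc['exonic_ndd_associated']} NDD-associated "
        f"({fc['pct_exonic_ndd']}%); {fc['exonic_ndd_nonsynonymous']} in the "
        "nonsynonymous NDD catalog"
    )
    for name in ("phenotype", "consequence", "origin", "pathogenicity", "domain_burden"):
        path = args.catalog / f"summary_{name}.tsv"
        if path.exists():
            print(f"\n{name}:")
            print(pd.read_csv(path, sep="\t").to_string(index=False))


if __name__ == "__main__":
    main()
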