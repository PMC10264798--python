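#!/usr/bin/env python
"""Harmonize the source exports: ingest every dialect, lift GRCh38 records,
normalize HGVS, deduplicate across sources, and report the cross-database
overlap table.

    python analysis/02_harmonize.py --exports results/simulated --out results/harmonized
"""

import argparse
from pathlib import Path

from ctcf_catalog.harmonize import source_overlap_table
from ctcf_catalog.pipeline import harmonize_export_dir


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--exports", type=Path, default=Path("results/simulated"))
    parser.add_argument("--out", type=Path, default=Path("results/harmonized"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    catalog, stats, exclusions = harmonize_export_dir(args.exports)
    table = source_overlap_table(stats)
    table.to_csv(args.out / "source_overlap.tsv", sep="\t", index=False)

    print(
        f"{stats['n_records']} records -> {stats['n_distinct']} distinct variants "
        f"({stats['n_duplicate_records']} duplicate records, "
        f"{stats['n_excluded']} excluded)"
    )
    print(
        f"{stats['n_in_multiple_sources']} variants "
        f"({100 * stats['n_in_multiple_sources'] / stats['n_distinct']:.0f}%) "
        "found in more than one source"
    )
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
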