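#!/usr/bin/env python
"""Curate the harmonized SNV catalog: classify phenotypes, assign origin,
reclassify pathogenicity, and write the exonic NDD catalog plus summary
tables. Harmonization (fast) is re-run from the exports so every output in
the catalog directory derives from one deterministic pass.

    python analysis/03_curate_snvs.py --exports results/simulated --out results/catalog
"""

import argparse
from pathlib import Path

from ctcf_catalog.pipeline import curate_snv_catalog, harmonize_export_dir
from ctcf_catalog.report import write_bundle


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--exports", type=Path, default=Path("results/simulated"))
    parser.add_argument("--out", type=Path, default=Path("results/catalog"))
    args = parser.parse_args()

    catalog, stats, exclusions = harmonize_export_dir(args.exports)
    bundle = curate_snv_catalog(catalog, stats, exclusions)
    write_bundle(bundle, args.out)

    fc = bundle.filter_counts
    print(
        f"{fc['distinct_variants']} distinct variants: {fc['exonic']} exonic, "
        f"{fc['exonic_ndd_associated']} NDD-associated "
        f"({fc['pct_exonic_ndd']}%), {fc['exonic_ndd_nonsynonymous']} "
        "nonsynonymous in the final NDD catalog"
    )
    print(f"catalog tables written to {args.out}")


if __name__ == "__main__":
    main()
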