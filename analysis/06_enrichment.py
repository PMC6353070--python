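#!/usr/bin/env python
"""GO term enrichment of differentially abundant proteins.

Splits the label-free differential results by direction (higher or lower
with resistant starch) and by origin (host vs bacterial), then runs the
one-sided Fisher exact test for each GO term against the quantified
universe, BH-corrected across all tested terms. Writes one table per
(origin, direction) analysis.
"""

import argparse
from pathlib import Path

import pandas as pd

from metaproteo.enrichment import enrichment_analysis
from metaproteo.io import read_fasta, read_go_annotations, write_provenance
def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    fixture = args.outdir / "fixture"

    catalog = read_fasta(fixture / "proteins.fasta")
    annotations = read_go_annotations(fixture / "go_annotations.tsv")
    diff = pd.read_csv(args.outdir / "diff_nsaf.tsv", sep="\t", index_col=0)
    host = catalog.is_host

    for origin in ("host", "bacterial"):
        origin_accs = diff.index[host.reindex(diff.index) == (origin == "host")]
        sub = diff.loc[origin_accs]
        universe = set(origin_accs)
        for direction, mask in (
            ("up_in_rs", sub["significant_05"] & (sub["log2fc"] > 0)),
            ("down_in_rs", sub["significant_05"] & (sub["log2fc"] < 0)),
        ):
            test = set(sub.index[mask])
            if len(test) < 3:
                print(f"{origin} {direction}: only {len(test)} proteins, skipped")
                continue
            table = enrichment_analysis(test, universe - test, annotations)
            out = args.outdir / f"go_{origin}_{direction}.tsv"
            table.to_csv(out, sep="\t", index=False)
            top = table.iloc[0] if len(table) else None
            label = f"{top.go_id} (p {top.p:.2e})" if top is not None else "none"
            print(f"{origin} {direction}: {len(test)} test proteins, "
                  f"{len(table)} terms at FDR<0.05; top: {label}")

    write_provenance(args.outdir / "provenance_enrichment.json", "enrichment", vars(args))


if __name__ == "__main__":
    main()
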