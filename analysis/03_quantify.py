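#!/usr/bin/env python
"""Protein quantification on three scales.

Applies the quantifiability filter (>= 2 unique peptides and >= 3 non-zero
values in one diet group), then produces NSAF, relative-iBAQ and TMT
ratio-to-pool matrices, log2-transforms them and imputes missing values
from a downshifted normal. Writes one matrix and one imputation mask per
method.
"""

import argparse
from pathlib import Path

import pandas as pd

from metaproteo.io import read_fasta, read_matrix, read_tmt, write_matrix, write_provenance
from metaproteo.pipeline import theoretical_counts
from metaproteo.qc import FilterPolicy, apply_protein_filters
from metaproteo.quantify import (
    ImputePolicy,
    impute,
    log2_transform,
    nsaf,
    relative_ibaq,
    tmt_ratio_to_pool,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    fixture = args.outdir / "fixture"

    catalog = read_fasta(fixture / "proteins.fasta")
    counts = read_matrix(args.outdir / "counts.tsv")
    intensities = read_matrix(args.outdir / "intensities.tsv")
    groups = pd.read_csv(fixture / "samples.tsv", sep="\t", index_col=0)["group"].to_dict()
    groups = {s: g for s, g in groups.items() if s in counts.columns}
    uniq = pd.read_csv(args.outdir / "unique_peptides.tsv", sep="\t", index_col=0)[
        "unique_peptides"
    ]

    policy = FilterPolicy()
    kept = apply_protein_filters(counts, policy, groups, uniq)
    print(f"quantifiable proteins: {len(kept)}/{len(counts)}")
    counts = counts.loc[kept]
    intensities = intensities.reindex(index=kept)

    matrices = {
        "nsaf": nsaf(counts, catalog.lengths),
        "ribaq": relative_ibaq(intensities, theoretical_counts(catalog)),
    }
    blocks = [read_tmt(p) for p in sorted(fixture.glob("tmt_batch*.csv"))]
    tmt = tmt_ratio_to_pool(blocks)
    tmt.values = tmt.values.loc[:, [s for s in tmt.values.columns if s in groups]]
    matrices["tmt"] = tmt

    for name, matrix in matrices.items():
        logged = log2_transform(matrix)
        complete = impute(logged, ImputePolicy(seed=args.seed))
        write_matrix(complete.values, args.outdir / f"{name}_log2_imputed.tsv")
        write_matrix(
            complete.imputed_mask.astype(int), args.outdir / f"{name}_imputed_mask.tsv"
        )
        frac = complete.imputed_mask.to_numpy().mean()
        print(f"  {name}: {complete.values.shape[0]} features, {frac:.1%} cells imputed")

    write_provenance(args.outdir / "provenance_quantify.json", "quantify", vars(args))


if __name__ == "__main__":
    main()
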