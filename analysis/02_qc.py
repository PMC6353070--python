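#!/usr/bin/env python
"""Identification and sample QC.

Filters PSMs to 1% target-decoy FDR, requires two unique peptides per
protein, computes each sample's host:bacteria spectral-count ratio, and
excludes robust-z outlier samples. Writes the retained count and intensity
matrices restricted to the surviving samples.
"""

import argparse
from pathlib import Path

import pandas as pd

from metaproteo.io import psms_to_frame, read_fasta, read_psm_table, write_matrix, write_provenance
from metaproteo.qc import (
    FilterPolicy,
    count_unique_peptides,
    filter_psms_by_fdr,
    flag_outliers,
    host_bacteria_ratio,
    intensity_matrix,
    spectral_count_matrix,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--fdr", type=float, default=0.01)
    ap.add_argument("--outlier-z", type=float, default=3.0)
    args = ap.parse_args()
    fixture = args.outdir / "fixture"

    psms = psms_to_frame(read_psm_table(fixture / "psms.tsv"))
    catalog = read_fasta(fixture / "proteins.fasta")
    retained, threshold = filter_psms_by_fdr(psms, args.fdr)
    print(f"FDR {args.fdr:.0%}: score threshold {threshold:.2f}, "
          f"{len(retained)}/{int((~psms.is_decoy).sum())} target PSMs retained")

    uniq = count_unique_peptides(retained)
    counts = spectral_count_matrix(retained)
    intensities = intensity_matrix(retained)

    ratios = host_bacteria_ratio(counts, catalog.is_host)
    excluded = flag_outliers(ratios, threshold=args.outlier_z)
    print(f"host:bacteria ratio median {ratios.median():.3f}; excluded samples: {excluded or 'none'}")

    kept_samples = [s for s in counts.columns if s not in excluded]
    write_matrix(counts[kept_samples], args.outdir / "counts.tsv")
    write_matrix(intensities[kept_samples], args.outdir / "intensities.tsv")
    uniq.rename_axis("accession").to_csv(args.outdir / "unique_peptides.tsv", sep="\t")
    ratios.rename_axis("sample_id").to_csv(args.outdir / "host_bacteria_ratio.tsv", sep="\t")
    pd.Series(excluded, name="sample_id").to_csv(
        args.outdir / "excluded_samples.tsv", sep="\t", index=False
    )
    print(f"wrote matrices for {len(kept_samples)} samples under {args.outdir}/")

    write_provenance(args.outdir / "provenance_qc.json", "qc", vars(args))


if __name__ == "__main__":
    main()
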