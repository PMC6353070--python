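"""Taxonomic rollup of protein abundances, taxon-level testing, diversity.

A taxonomic unit's abundance in a sample is the sum of spectral counts of
the proteins whose lineage resolves to that unit at the requested rank,
divided by the sample's total spectral count. The resulting taxon table is
compositional: columns sum to exactly 1 including the "unassigned" row
(features whose lineage lacks the rank). Host proteins roll up under their
own lineage (e.g. Chordata at phylum rank), so the host fraction stays
visible alongside the microbiome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import LineageTable, ProteinCatalog, RANKS
from .quantify import ImputePolicy, impute, log2_transform
from .stats import EbPrior, moderated_t_test

__all__ = [
    "TaxonTable",
    "UNASSIGNED",
    "rollup",
    "taxa_differential",
    "alpha_diversity",
    "phylum_ratio",
]

UNASSIGNED = "unassigned"


@dataclass
class TaxonTable:
    """Taxon x sample relative abundances at one rank.

    ``taxonomy`` maps taxon name -> full lineage path (for BIOM export).
    """

    values_frame: pd.DataFrame
    rank: str
    taxonomy: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        colsums = self.values_frame.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("taxon table columns must sum to 1")
        if (self.values_frame < 0).to_numpy().any():
            raise ValueError("abundances must be nonnegative")

    @property
    def taxa(self) -> pd.Index:
        return self.values_frame.index

    @property
    def samples(self) -> pd.Index:
        return self.values_frame.columns


def rollup(
    counts_matrix: pd.DataFrame,
    catalog: ProteinCatalog,
    lineage: LineageTable,
    rank: str,
) -> TaxonTable:
    """Sum protein spectral counts into taxonomic units at ``rank`` and
    normalize by each sample's total count.

    ``rank`` is one of the seven canonical ranks or "lowest" (most specific
    named rank per taxid). Features with taxid absent from the lineage
    table, or whose lineage lacks the rank, accrue to "unassigned".
    """
    totals = counts_matrix.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    taxids = catalog.proteins["taxid"].reindex(counts_matrix.index)
    if taxids.isna().any():
        raise ValueError(
            f"feature(s) missing from catalog: {list(counts_matrix.index[taxids.isna()][:3])}"
        )
    names_at_rank = lineage.name_at(rank)
    taxon_of = taxids.map(names_at_rank).fillna(UNASSIGNED)
    summed = counts_matrix.groupby(taxon_of.values).sum()
    if UNASSIGNED not in summed.index:
        summed.loc[UNASSIGNED] = 0.0
    rel = summed.div(totals, axis=1)
    rel = rel.sort_index()
    rel.index.name = "taxon"

    taxonomy: dict[str, tuple[str, ...]] = {}
    depth = len(RANKS) if rank == "lowest" else RANKS.index(rank) + 1
    for taxon in rel.index:
        if taxon == UNASSIGNED:
            taxonomy[taxon] = (UNASSIGNED,)
            continue
        tids = names_at_rank[names_at_rank == taxon].index
        row = lineage.frame.loc[tids[0], list(RANKS)]
        taxonomy[taxon] = tuple(str(v) for v in row.iloc[:depth].dropna())
    return TaxonTable(values_frame=rel, rank=rank, taxonomy=taxonomy)


def taxa_differential(
    taxon_table: TaxonTable,
    groups: Mapping[str, str],
    impute_policy: ImputePolicy | None = None,
    prior: EbPrior | None = None,
) -> pd.DataFrame:
    """Moderated t-test over taxa with BH adjustment across taxa at this rank.

    Relative abundances are log2-transformed (zeros become missing) and
    missing cells imputed with the same downshifted-normal policy used for
    proteins before testing. The "unassigned" bucket is excluded from
    testing — it is a remainder, not a taxon.
    """
    values = taxon_table.values_frame.drop(index=UNASSIGNED, errors="ignore")
    policy = impute_policy or ImputePolicy()
    logged = log2_transform(values)
    complete = impute(logged, policy)
    complete.sample_groups = dict(groups)
    return moderated_t_test(complete, groups, prior=prior)


def alpha_diversity(
    taxon_table: TaxonTable,
    index: str = "shannon",
    detection_floor: float = 0.0,
) -> pd.DataFrame:
    """Per-sample richness and/or Shannon entropy.

    Richness S counts taxa with abundance above ``detection_floor``;
    Shannon H = -sum a_i ln a_i over detected taxa after renormalizing
    their abundances to sum to 1. The unassigned bucket is excluded.
    Returns a DataFrame indexed by sample with columns from
    {"richness", "shannon"} (both when index="both").
    """
    if index not in ("richness", "shannon", "both"):
        raise ValueError(f"unknown diversity index {index!r}")
    if detection_floor < 0:
        raise ValueError("detection_floor must be >= 0")
    values = taxon_table.values_frame.drop(index=UNASSIGNED, errors="ignore")
    out = {}
    for sample in values.columns:
        a = values[sample]
        detected = a[a > detection_floor]
        if detected.empty:
            raise ValueError(f"sample {sample!r} has no detected taxa")
        row = {}
        if index in ("richness", "both"):
            row["richness"] = int(len(detected))
        if index in ("shannon", "both"):
            p = detected / detected.sum()
            row["shannon"] = float(-(p * np.log(p)).sum())
        out[sample] = row
    return pd.DataFrame.from_dict(out, orient="index").rename_axis("sample")


def phylum_ratio(
    taxon_table: TaxonTable,
    numerator: str = "Bacteroidetes",
    denominator: str = "Firmicutes",
) -> pd.Series:
    """Per-sample abundance ratio of two phyla (e.g. Bacteroidetes:Firmicutes).

    Zero denominator yields +inf for that sample. The table must be at
    phylum rank (or contain both names at its rank).
    """
    values = taxon_table.values_frame
    for name in (numerator, denominator):
        if name not in values.index:
            raise ValueError(
                f"taxon {name!r} not in table; available: {list(values.index)}"
            )
    num = values.loc[numerator]
    den = values.loc[denominator]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    ratio = ratio.where(den > 0, np.inf)
    return ratio.rename(f"{numerator}:{denominator}")
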