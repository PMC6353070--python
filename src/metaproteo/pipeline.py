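"""End-to-end compositions of the pipeline stages.

Thin orchestration over qc, quantify and stats: each function takes the
raw simulated (or parsed) inputs for one quantification route and returns
the per-feature differential-abundance table. The analysis drivers and
the acceptance checks run through these, so the exact stage order —
filter, quantify, log2, impute, moderated t, BH — lives in one place.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .io import ProteinCatalog, TmtBlock
from .quantify import (
    AbundanceMatrix,
    ImputePolicy,
    impute,
    log2_transform,
    nsaf,
    relative_ibaq,
    theoretical_peptide_count,
    tmt_ratio_to_pool,
)
from .stats import moderated_t_test

__all__ = [
    "differential_from_counts",
    "differential_from_intensities",
    "differential_from_tmt",
    "theoretical_counts",
]


def theoretical_counts(catalog: ProteinCatalog) -> pd.Series:
    """Observable tryptic peptides per protein (iBAQ denominator)."""
    return catalog.proteins["sequence"].map(theoretical_peptide_count).rename("theoretical_peptides")


def _finish(matrix: AbundanceMatrix, groups: Mapping[str, str], policy: ImputePolicy) -> pd.DataFrame:
    logged = log2_transform(matrix)
    complete = impute(logged, policy)
    complete.sample_groups = dict(groups)
    return moderated_t_test(complete, groups)


def differential_from_counts(
    counts: pd.DataFrame,
    lengths: pd.Series,
    groups: Mapping[str, str],
    policy: ImputePolicy | None = None,
) -> pd.DataFrame:
    """Spectral counts -> NSAF -> log2 -> impute -> moderated t."""
    return _finish(nsaf(counts, lengths), groups, policy or ImputePolicy())


def differential_from_intensities(
    intensities: pd.DataFrame,
    theo_counts: pd.Series,
    groups: Mapping[str, str],
    policy: ImputePolicy | None = None,
) -> pd.DataFrame:
    """Precursor intensities -> relative iBAQ -> log2 -> impute -> moderated t."""
    return _finish(relative_ibaq(intensities, theo_counts), groups, policy or ImputePolicy())


def differential_from_tmt(
    blocks: Sequence[TmtBlock],
    groups: Mapping[str, str],
    policy: ImputePolicy | None = None,
) -> pd.DataFrame:
    """TMT reporter blocks -> ratio-to-pool -> log2 -> impute -> moderated t."""
    matrix = tmt_ratio_to_pool(blocks)
    groups = {s: g for s, g in groups.items() if s in matrix.values.columns}
    return _finish(matrix, groups, policy or ImputePolicy())
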