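"""Identification-quality and sample-quality filters.

PSMs are filtered by target-decoy FDR: with targets and decoys scored on a
common scale, the estimated FDR at score threshold t is
#decoys(score >= t) / #targets(score >= t), and the retained set is the
targets at the most permissive threshold whose estimate stays at or below
the requested rate. Proteins must then be supported by at least two unique
peptides (I and L equated) and carry enough non-zero abundances in at
least one diet group to be quantifiable. Sample-level QC computes each
sample's host:bacteria spectral-count ratio and flags extreme samples by a
median/MAD robust z-score of the log ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PsmRecord, psms_to_frame

__all__ = [
    "FilterPolicy",
    "filter_psms_by_fdr",
    "count_unique_peptides",
    "apply_protein_filters",
    "spectral_count_matrix",
    "intensity_matrix",
    "host_bacteria_ratio",
    "flag_outliers",
]


@dataclass
class FilterPolicy:
    """Identification and quantifiability thresholds."""

    psm_fdr: float = 0.01
    min_unique_peptides: int = 2
    min_nonzero_per_group: int = 3
    outlier_z: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.psm_fdr < 1:
            raise ValueError("psm_fdr must be in (0, 1)")
        if self.min_unique_peptides < 1 or self.min_nonzero_per_group < 1:
            raise ValueError("count thresholds must be >= 1")


def filter_psms_by_fdr(
    psms: Iterable[PsmRecord] | pd.DataFrame, fdr_target: float = 0.01
) -> tuple[pd.DataFrame, float]:
    """Target-decoy FDR filter.

    Returns (retained target PSMs, score threshold). The threshold is the
    smallest score at which #decoys/#targets at-or-above stays <= target,
    which makes retained sets nested under stricter targets. If no
    threshold achieves the target the retained set is empty (with a
    warning), not an exception.
    """
    df = psms_to_frame(psms)
    if not (~df["is_decoy"]).any():
        raise ValueError("no target PSMs present")
    if not np.isfinite(df["score"]).all():
        raise ValueError("PSM scores must be finite")
    order = df.sort_values("score", ascending=False, kind="stable")
    is_decoy = order["is_decoy"].to_numpy()
    scores = order["score"].to_numpy()
    cum_decoys = np.cumsum(is_decoy)
    cum_targets = np.cumsum(~is_decoy)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(cum_targets > 0, cum_decoys / np.maximum(cum_targets, 1), np.inf)
    # evaluate at the last entry of each tied score block (the full set >= t)
    last_of_block = np.r_[scores[1:] != scores[:-1], True]
    ok = (fdr <= fdr_target) & last_of_block
    if not ok.any():
        warnings.warn(f"no score threshold achieves FDR <= {fdr_target}; retaining nothing")
        return df.iloc[0:0], math.inf
    threshold = float(scores[np.flatnonzero(ok)[-1]])
    retained = df[(~df["is_decoy"]) & (df["score"] >= threshold)]
    return retained, threshold


def count_unique_peptides(psms: Iterable[PsmRecord] | pd.DataFrame) -> pd.Series:
    """Unique supporting peptides per accession.

    A peptide (sequence with I and L equated) counts as unique evidence
    only when every PSM carrying it maps to exactly one accession.
    """
    df = psms_to_frame(psms)
    df = df[~df["is_decoy"]]
    pep = df["peptide"].str.replace("I", "L")
    mapping = pd.DataFrame({"peptide": pep, "proteins": df["proteins"]}).drop_duplicates()
    per_pep = mapping.groupby("peptide")["proteins"].agg(
        lambda accs: set(a for entry in accs for a in entry.split(";"))
    )
    unique = per_pep[per_pep.map(len) == 1]
    counts: dict[str, int] = {}
    for accs in unique:
        (acc,) = accs
        counts[acc] = counts.get(acc, 0) + 1
    return pd.Series(counts, dtype=int).rename("unique_peptides")


def spectral_count_matrix(psms: Iterable[PsmRecord] | pd.DataFrame) -> pd.DataFrame:
    """Protein x sample spectral counts; shared PSMs accrue to every mapped
    accession (the catalog's protein assignment is taken as given)."""
    df = psms_to_frame(psms)
    df = df[~df["is_decoy"]].copy()
    df["proteins"] = df["proteins"].str.split(";")
    long = df.explode("proteins")
    mat = long.pivot_table(
        index="proteins", columns="sample_id", values="spectral_count", aggfunc="sum"
    ).fillna(0)
    mat.index.name = "feature"
    return mat


def intensity_matrix(psms: Iterable[PsmRecord] | pd.DataFrame) -> pd.DataFrame:
    """Protein x sample summed precursor intensities (NaN where none observed)."""
    df = psms_to_frame(psms)
    df = df[~df["is_decoy"]].copy()
    df["proteins"] = df["proteins"].str.split(";")
    long = df.explode("proteins")
    mat = long.pivot_table(
        index="proteins",
        columns="sample_id",
        values="precursor_intensity",
        aggfunc="sum",
    )
    mat.index.name = "feature"
    return mat


def apply_protein_filters(
    counts_matrix: pd.DataFrame,
    policy: FilterPolicy,
    groups: Mapping[str, str],
    unique_peptides: pd.Series | Mapping[str, int],
) -> pd.Index:
    """Accessions retained by the unique-peptide and quantifiability rules.

    A protein survives iff it has >= policy.min_unique_peptides unique
    peptides AND >= policy.min_nonzero_per_group non-zero abundances in at
    least one diet group.
    """
    unknown = set(groups) - set(counts_matrix.columns)
    if unknown:
        raise ValueError(f"group labels for unknown sample(s): {sorted(unknown)}")
    uniq = pd.Series(unique_peptides, dtype=float).reindex(counts_matrix.index).fillna(0)
    enough_peptides = uniq >= policy.min_unique_peptides
    group_names = sorted(set(groups.values()))
    nonzero_ok = pd.Series(False, index=counts_matrix.index)
    for g in group_names:
        cols = [s for s in counts_matrix.columns if groups.get(s) == g]
        if not cols:
            continue
        nz = (counts_matrix[cols].fillna(0) != 0).sum(axis=1)
        nonzero_ok |= nz >= policy.min_nonzero_per_group
    return counts_matrix.index[enough_peptides & nonzero_ok]


def host_bacteria_ratio(
    counts_matrix: pd.DataFrame, host_flags: pd.Series
) -> pd.Series:
    """Per-sample ratio of host to bacterial spectral counts.

    Samples with zero bacterial counts get +inf (flagged via warning).
    """
    flags = host_flags.reindex(counts_matrix.index)
    if flags.isna().any():
        raise ValueError("host flag missing for some features")
    if not flags.any() or flags.all():
        raise ValueError("catalog must contain both host and bacterial proteins")
    host = counts_matrix[flags.astype(bool)].sum(axis=0)
    bact = counts_matrix[~flags.astype(bool)].sum(axis=0)
    with np.errstate(divide="ignore"):
        ratio = host / bact
    ratio = ratio.where(bact > 0, np.inf)
    if np.isinf(ratio).any():
        warnings.warn(
            f"sample(s) with zero bacterial counts: {list(ratio.index[np.isinf(ratio)])}"
        )
    return ratio.rename("host_bacteria_ratio")


def flag_outliers(ratios: pd.Series, threshold: float = 3.0) -> list[str]:
    """Samples whose log host:bacteria ratio is a robust-z outlier.

    z = (log r - median) / (1.4826 * MAD); samples with |z| > threshold are
    excluded. Scale-invariant: multiplying all ratios by a constant shifts
    every log equally and changes nothing. MAD = 0 yields no exclusions
    (with a warning) rather than flagging everything.
    """
    if len(ratios) < 4:
        raise ValueError("need >= 4 samples to flag outliers")
    log_r = np.log(ratios.astype(float))
    med = float(np.median(log_r[np.isfinite(log_r)]))
    mad = float(np.median(np.abs(log_r[np.isfinite(log_r)] - med)))
    if mad == 0:
        warnings.warn("MAD of log ratios is 0; no outliers flagged")
        return []
    z = (log_r - med) / (1.4826 * mad)
    z = z.where(np.isfinite(log_r), np.inf)  # infinite ratios are always extreme
    return list(ratios.index[np.abs(z) > threshold])
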