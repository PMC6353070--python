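"""Protein abundance scales: NSAF, relative iBAQ, TMT ratio-to-pool.

All three scales are compositional per sample. NSAF is length-normalized
spectral counting: NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j). Relative
iBAQ divides summed precursor intensity by the number of theoretically
observable tryptic peptides and renormalizes to the per-sample sum. TMT
abundances are reporter-intensity ratios to a pooled reference channel,
computed per batch after equalizing channel sums.

Downstream statistics run on log2 values with missing-not-at-random cells
imputed from a downshifted normal: N(mean - shift_sds * sd,
(width_factor * sd)^2) of the observed values, the Perseus-style convention
for left-censored proteomics data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import TmtBlock

__all__ = [
    "AbundanceMatrix",
    "ImputePolicy",
    "nsaf",
    "theoretical_peptide_count",
    "relative_ibaq",
    "tmt_ratio_to_pool",
    "log2_transform",
    "impute",
]

SCALES = ("counts", "NSAF", "riBAQ", "tmt_ratio", "log2")


@dataclass
class AbundanceMatrix:
    """Feature x sample abundances in a named scale.

    ``imputed_mask`` is True exactly where a value was filled in by
    :func:`impute`; it is all-False for raw matrices.
    """

    values: pd.DataFrame
    scale: str
    imputed_mask: pd.DataFrame | None = None
    sample_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.imputed_mask is None:
            self.imputed_mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )

    def copy_with(self, values: pd.DataFrame, scale: str | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(
            values=values,
            scale=scale or self.scale,
            imputed_mask=self.imputed_mask.copy(),
            sample_groups=self.sample_groups,
        )


@dataclass
class ImputePolicy:
    """Downshifted-normal imputation parameters.

    width_factor: imputation sd as a fraction of the observed sd (0.30).
    shift_sds: downshift of the imputation mean in observed-sd units (2.0).
    per_sample: estimate mean/sd per sample (column-wise) when True, else
    from the whole matrix.
    """

    width_factor: float = 0.30
    shift_sds: float = 2.0
    seed: int = 0
    per_sample: bool = True

    def __post_init__(self) -> None:
        if self.width_factor <= 0:
            raise ValueError("width_factor must be > 0")
        if self.shift_sds < 0:
            raise ValueError("shift_sds must be >= 0")


def _as_frame(m: AbundanceMatrix | pd.DataFrame) -> pd.DataFrame:
    return m.values if isinstance(m, AbundanceMatrix) else m


def nsaf(counts: pd.DataFrame, lengths: pd.Series) -> AbundanceMatrix:
    """Normalized spectral abundance factors from a count matrix.

    ``lengths`` gives each protein's residue count L; columns of the result
    sum to 1 over the retained features.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError(
            f"missing length for feature(s) {list(lengths.index[lengths.isna()][:3])}"
        )
    if (lengths <= 0).any():
        raise ValueError("protein lengths must be positive")
    if (counts.fillna(0) < 0).to_numpy().any():
        raise ValueError("spectral counts must be nonnegative")
    saf = counts.div(lengths, axis=0)
    totals = saf.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero.index)}")
    return AbundanceMatrix(values=saf.div(totals, axis=1), scale="NSAF")


def theoretical_peptide_count(
    sequence: str, min_len: int = 7, max_len: int = 30
) -> int:
    """Number of fully-tryptic peptides with length in [min_len, max_len].

    Cleaves C-terminal to K or R except before P (the KP/RP rule), zero
    missed cleavages.
    """
    if not sequence:
        warnings.warn("empty sequence has no theoretical peptides")
        return 0
    peptides = tryptic_digest(sequence)
    return sum(min_len <= len(p) <= max_len for p in peptides)


def tryptic_digest(sequence: str) -> list[str]:
    """Fully-tryptic fragments of ``sequence`` (no length filter)."""
    peptides = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            peptides.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        peptides.append(sequence[start:])
    return peptides


def relative_ibaq(
    intensities: pd.DataFrame, theoretical_counts: pd.Series
) -> AbundanceMatrix:
    """Relative iBAQ: intensity / theoretical peptide count, renormalized to
    the per-sample sum over observed features. Missing stays missing."""
    theo = theoretical_counts.reindex(intensities.index)
    carrying = intensities.notna().any(axis=1)
    bad = intensities.index[carrying & ((theo.isna()) | (theo < 1))]
    if len(bad):
        raise ValueError(
            f"feature(s) with intensity but no observable tryptic peptides: {list(bad[:3])}"
        )
    ibaq = intensities.div(theo, axis=0)
    totals = ibaq.sum(axis=0, skipna=True)
    if (totals == 0).any():
        raise ValueError(
            f"sample(s) with no observed intensity: {list(totals.index[totals == 0])}"
        )
    return AbundanceMatrix(values=ibaq.div(totals, axis=1), scale="riBAQ")


def tmt_ratio_to_pool(blocks: Sequence[TmtBlock]) -> AbundanceMatrix:
    """Reporter-ion ratios to the pooled reference channel, per batch.

    Within each batch, channel columns are first normalized to equal sums
    (computed over features observed in every channel of the batch), then
    each feature's value is channel / pool. Batches are concatenated over
    the union of features; a feature missing from a batch is missing for
    that batch's samples. Features whose pool intensity is zero or missing
    are missing too (counted in a warning).
    """
    if not blocks:
        raise ValueError("no TMT blocks given")
    pieces = []
    n_zero_pool = 0
    for block in blocks:
        inten = block.intensities.astype(float)
        complete = inten.dropna()
        if complete.empty:
            raise ValueError(f"batch {block.batch_id}: no feature observed in all channels")
        sums = complete.sum(axis=0)
        if (sums <= 0).any():
            raise ValueError(f"batch {block.batch_id}: channel with nonpositive total")
        norm = inten.div(sums / sums.mean(), axis=1)
        pool = norm[block.pool_channel]
        zero_pool = pool.isna() | (pool == 0)
        n_zero_pool += int(zero_pool.sum())
        ratios = norm.div(pool.where(~zero_pool), axis=0)
        ratios = ratios.drop(columns=block.pool_channel)
        ratios.columns = [block.sample_map[ch] for ch in ratios.columns]
        pieces.append(ratios)
    if n_zero_pool:
        warnings.warn(f"{n_zero_pool} feature/batch pairs dropped for zero or missing pool intensity")
    out = pd.concat(pieces, axis=1)
    return AbundanceMatrix(values=out, scale="tmt_ratio")


def log2_transform(matrix: AbundanceMatrix | pd.DataFrame) -> AbundanceMatrix:
    """log2 of positive entries; zeros and missing become missing.

    Zero counts are left-censored observations in this workflow, not
    evidence of absence, so they enter the imputation path rather than
    becoming -inf.
    """
    values = _as_frame(matrix)
    out = values.where(values > 0)
    result = AbundanceMatrix(
        values=np.log2(out),
        scale="log2",
        sample_groups=getattr(matrix, "sample_groups", None),
    )
    return result


def impute(matrix: AbundanceMatrix | pd.DataFrame, policy: ImputePolicy) -> AbundanceMatrix:
    """Fill missing log2 values from a downshifted normal distribution.

    Observed cells are never modified; the returned ``imputed_mask`` marks
    the filled cells. Draws are deterministic given ``policy.seed``.
    """
    values = _as_frame(matrix).copy()
    rng = np.random.default_rng(policy.seed)
    mask = values.isna()
    if policy.per_sample:
        for col in values.columns:
            _impute_column(values, col, mask[col], policy, rng)
    else:
        valid = values.to_numpy()[~mask.to_numpy()]
        if valid.size < 2:
            raise ValueError("need >= 2 observed values to impute")
        mu, sd = float(valid.mean()), float(valid.std(ddof=1))
        if sd == 0:
            warnings.warn("observed sd is 0; imputing at the mean")
        n_missing = int(mask.to_numpy().sum())
        draws = rng.normal(mu - policy.shift_sds * sd, policy.width_factor * sd, n_missing)
        arr = values.to_numpy()
        arr[mask.to_numpy()] = draws
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return AbundanceMatrix(
        values=values,
        scale="log2",
        imputed_mask=mask,
        sample_groups=getattr(matrix, "sample_groups", None),
    )


def _impute_column(
    values: pd.DataFrame,
    col: str,
    col_mask: pd.Series,
    policy: ImputePolicy,
    rng: np.random.Generator,
) -> None:
    observed = values[col][~col_mask]
    if len(observed) < 2:
        raise ValueError(f"sample {col!r}: need >= 2 observed values to impute")
    mu, sd = float(observed.mean()), float(observed.std(ddof=1))
    if sd == 0:
        warnings.warn(f"sample {col!r}: observed sd is 0; imputing at the mean")
    draws = rng.normal(mu - policy.shift_sds * sd, policy.width_factor * sd, int(col_mask.sum()))
    values.loc[col_mask, col] = draws
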