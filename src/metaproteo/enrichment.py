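"""Fisher-exact GO term over-representation analysis.

For each GO term, a 2x2 table counts proteins annotated with the term
versus not, in the test list (differentially abundant proteins) versus the
reference (the rest of the universe). Significance is the one-sided upper
tail of the hypergeometric distribution — the probability of drawing at
least the observed number of annotated proteins into the test list — with
Benjamini-Hochberg control across all tested terms (namespaces pooled).
Under-representation analyses are run by swapping in the complementary
protein list as the test set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .stats import bh_adjust

__all__ = [
    "Contingency",
    "build_contingency",
    "fisher_upper",
    "enrichment_analysis",
]

NAMESPACES = ("BP", "MF", "CC")


@dataclass(frozen=True)
class Contingency:
    """Counts for one term: annotated/unannotated x test/reference."""

    nr_test: int
    nr_ref: int
    non_annot_test: int
    non_annot_ref: int

    def __post_init__(self) -> None:
        if min(self.nr_test, self.nr_ref, self.non_annot_test, self.non_annot_ref) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def n_test(self) -> int:
        return self.nr_test + self.non_annot_test

    @property
    def n_total(self) -> int:
        return self.nr_test + self.nr_ref + self.non_annot_test + self.non_annot_ref

    @property
    def n_annotated(self) -> int:
        return self.nr_test + self.nr_ref


def build_contingency(
    test_accessions: Iterable[str],
    reference_accessions: Iterable[str],
    term: str,
    annotations: Mapping[str, set[tuple[str, str]] | set[str]],
    ontology: Mapping[str, set[str]] | None = None,
) -> Contingency:
    """Count annotated vs unannotated accessions in test vs reference.

    ``annotations`` maps accession -> set of GO ids (or (id, namespace)
    pairs). In flat mode (default) a protein is annotated with exactly its
    listed terms; if ``ontology`` supplies term -> descendant ids, a protein
    annotated with any descendant counts for the ancestor. Accessions
    absent from the annotation table count as unannotated.
    """
    test = set(test_accessions)
    ref = set(reference_accessions)
    if test & ref:
        raise ValueError("test and reference sets must be disjoint")
    match_ids = {term} | (set(ontology.get(term, ())) if ontology else set())

    def has_term(acc: str) -> bool:
        terms = annotations.get(acc, set())
        ids = {t[0] if isinstance(t, tuple) else t for t in terms}
        return bool(ids & match_ids)

    nr_test = sum(has_term(a) for a in test)
    nr_ref = sum(has_term(a) for a in ref)
    return Contingency(
        nr_test=nr_test,
        nr_ref=nr_ref,
        non_annot_test=len(test) - nr_test,
        non_annot_ref=len(ref) - nr_ref,
    )


def _log_hypergeom_pmf(k: np.ndarray, n_total: int, n_annot: int, n_test: int) -> np.ndarray:
    def log_binom(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    return (
        log_binom(n_annot, k)
        + log_binom(n_total - n_annot, n_test - k)
        - log_binom(n_total, n_test)
    )


def fisher_upper(c: Contingency) -> float:
    """One-sided Fisher p: P(X >= nr_test) for hypergeometric X.

    Population = all proteins in the analysis, successes = annotated
    proteins, draws = the test list. Summed in log space for stability at
    extreme tables.
    """
    if c.n_test == 0:
        raise ValueError("empty test universe")
    if c.n_annotated == 0 or c.n_annotated == c.n_total:
        return 1.0
    k_max = min(c.n_annotated, c.n_test)
    if c.nr_test == 0:
        return 1.0
    k = np.arange(c.nr_test, k_max + 1)
    log_terms = _log_hypergeom_pmf(k, c.n_total, c.n_annotated, c.n_test)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enrichment_analysis(
    test_accessions: Iterable[str],
    reference_accessions: Iterable[str],
    annotations: Mapping[str, set[tuple[str, str]]],
    namespaces: Sequence[str] = NAMESPACES,
    alpha: float = 0.05,
    go_names: Mapping[str, str] | None = None,
    ontology: Mapping[str, set[str]] | None = None,
    return_all: bool = False,
) -> pd.DataFrame:
    """Test every GO term with >= 1 annotated protein for over-representation.

    BH adjustment pools all tested terms across the requested namespaces
    (one analysis = one multiple-testing family). Returns rows with
    fdr < alpha sorted by (fdr, p), in the column layout
    go_id, go_name, namespace, fdr, p, nr_test, nr_ref, non_annot_test,
    non_annot_ref; ``return_all=True`` skips the significance cut.
    """
    test = set(test_accessions)
    ref = set(reference_accessions)
    if not test or not ref:
        raise ValueError("test and reference sets must be nonempty")
    terms: dict[tuple[str, str], None] = {}
    for acc in (*test, *ref):
        for go_id, ns in annotations.get(acc, set()):
            if ns in namespaces:
                terms[(go_id, ns)] = None
    rows = []
    for go_id, ns in terms:
        c = build_contingency(test, ref, go_id, annotations, ontology=ontology)
        rows.append(
            {
                "go_id": go_id,
                "go_name": (go_names or {}).get(go_id, go_id),
                "namespace": ns,
                "p": fisher_upper(c),
                "nr_test": c.nr_test,
                "nr_ref": c.nr_ref,
                "non_annot_test": c.non_annot_test,
                "non_annot_ref": c.non_annot_ref,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "go_id", "go_name", "namespace", "fdr", "p",
                "nr_test", "nr_ref", "non_annot_test", "non_annot_ref",
            ]
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out = out[
        ["go_id", "go_name", "namespace", "fdr", "p",
         "nr_test", "nr_ref", "non_annot_test", "non_annot_ref"]
    ]
    out = out.sort_values(["fdr", "p"], kind="stable").reset_index(drop=True)
    if return_all:
        return out
    return out[out["fdr"] < alpha].reset_index(drop=True)
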