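"""Readers and writers for the pipeline's external formats.

The canonical peptide-spectrum-match (PSM) exchange format is a TSV with
columns ``peptide, proteins, sample_id, score, is_decoy, spectral_count,
precursor_intensity``; ``proteins`` is a semicolon-separated accession list
and a missing precursor intensity is an empty cell (never 0 — zero is a
legitimate measurement). Abundance matrices are TSV with features as rows
and samples as columns, missing encoded as empty cells. Taxon tables can be
exported as BIOM v1 JSON ("OTU table", sparse) for interoperability with
microbiome tooling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ParseError",
    "PsmRecord",
    "ProteinCatalog",
    "LineageTable",
    "TmtBlock",
    "RANKS",
    "read_psm_table",
    "write_psm_table",
    "psms_to_frame",
    "read_fasta",
    "write_fasta",
    "read_lineage",
    "write_lineage",
    "read_go_annotations",
    "write_go_annotations",
    "read_tmt",
    "write_tmt",
    "read_matrix",
    "write_matrix",
    "write_provenance",
    "write_biom",
    "read_biom",
]

#: Canonical taxonomy ranks, coarsest to finest.
RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

PSM_COLUMNS = (
    "peptide",
    "proteins",
    "sample_id",
    "score",
    "is_decoy",
    "spectral_count",
    "precursor_intensity",
)


class ParseError(ValueError):
    """A file violated its schema; message carries the first offending line."""


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match.

    ``score`` is on the search engine's -10*log10(P) scale; ``is_decoy``
    marks matches against reversed/shuffled sequences used for FDR
    estimation.
    """

    peptide: str
    proteins: tuple[str, ...]
    sample_id: str
    score: float
    is_decoy: bool
    spectral_count: int
    precursor_intensity: float | None = None

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("PSM peptide must be nonempty")
        if not self.proteins:
            raise ValueError("PSM protein list must be nonempty")
        if self.spectral_count < 1:
            raise ValueError("spectral_count must be >= 1")


@dataclass
class ProteinCatalog:
    """Per-accession metadata: sequence, length, taxid, host flag, GO terms.

    ``proteins`` is indexed by accession with columns ``sequence`` (may be
    empty string when only the length is known), ``length`` (residues),
    ``taxid`` (int, -1 = unassigned) and ``is_host`` (bool). ``go`` maps
    accession -> set of (GO id, namespace) pairs, namespace in {BP, MF, CC}.
    """

    proteins: pd.DataFrame
    go: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = self.proteins.index[
            (self.proteins["sequence"].str.len() > 0)
            & (self.proteins["sequence"].str.len() != self.proteins["length"])
        ]
        if len(bad):
            raise ValueError(f"length != |sequence| for accession(s) {list(bad[:3])}")

    @property
    def accessions(self) -> pd.Index:
        return self.proteins.index

    @property
    def lengths(self) -> pd.Series:
        return self.proteins["length"]

    @property
    def is_host(self) -> pd.Series:
        return self.proteins["is_host"]

    def go_frame(self) -> pd.DataFrame:
        rows = [
            (acc, go_id, ns)
            for acc, terms in sorted(self.go.items())
            for go_id, ns in sorted(terms)
        ]
        return pd.DataFrame(rows, columns=["accession", "go_id", "namespace"])


@dataclass
class LineageTable:
    """taxid -> named ranks (NCBI-style); missing intermediate ranks are NaN."""

    frame: pd.DataFrame  # index taxid, columns RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.frame.columns]
        if missing:
            raise ValueError(f"lineage table lacks rank column(s) {missing}")

    def name_at(self, rank: str) -> pd.Series:
        """Taxon name of every taxid at ``rank``; NaN where the rank is a gap.

        ``rank='lowest'`` returns the most specific named rank per taxid.
        """
        if rank == "lowest":
            sub = self.frame[list(RANKS)]
            return sub.apply(
                lambda row: row.dropna().iloc[-1] if row.notna().any() else np.nan,
                axis=1,
            )
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS} or 'lowest'")
        return self.frame[rank]


@dataclass
class TmtBlock:
    """One TMT batch: reporter intensities (feature x channel) plus the
    channel -> sample map. Exactly one channel must be the pooled reference."""

    batch_id: str
    sample_map: dict[str, str]  # channel label -> sample id ("pool" for the reference)
    intensities: pd.DataFrame  # features x channel labels

    POOL = "pool"

    def __post_init__(self) -> None:
        pools = [ch for ch, s in self.sample_map.items() if s == self.POOL]
        if len(pools) != 1:
            raise ValueError(
                f"batch {self.batch_id}: expected exactly one pool channel, got {len(pools)}"
            )
        unknown = set(self.intensities.columns) - set(self.sample_map)
        if unknown:
            raise ValueError(f"batch {self.batch_id}: unmapped channel(s) {sorted(unknown)}")

    @property
    def pool_channel(self) -> str:
        return next(ch for ch, s in self.sample_map.items() if s == self.POOL)


# ---------------------------------------------------------------------------
# PSM tables


def _fail(path: Path, lineno: int, msg: str) -> None:
    raise ParseError(f"{path}:{lineno}: {msg}")


def read_psm_table(path: str | Path) -> list[PsmRecord]:
    """Read the canonical PSM TSV into typed records.

    Schema violations raise :class:`ParseError` naming the first bad line;
    unknown columns are ignored (preserved by frame-level readers).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        _fail(path, 1, f"missing column(s) {missing}")
    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            intensity = row.precursor_intensity
            rec = PsmRecord(
                peptide=row.peptide,
                proteins=tuple(p for p in row.proteins.split(";") if p),
                sample_id=row.sample_id,
                score=float(row.score),
                is_decoy=_parse_bool(row.is_decoy),
                spectral_count=int(row.spectral_count),
                precursor_intensity=float(intensity) if intensity != "" else None,
            )
        except (ValueError, TypeError) as exc:
            _fail(path, i, str(exc))
        records.append(rec)
    return records


def _parse_bool(s: str) -> bool:
    if s in ("True", "true", "1"):
        return True
    if s in ("False", "false", "0"):
        return False
    raise ValueError(f"invalid boolean {s!r}")


def psms_to_frame(psms: Iterable[PsmRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(psms, pd.DataFrame):
        return psms
    psms = list(psms)
    return pd.DataFrame(
        {
            "peptide": [p.peptide for p in psms],
            "proteins": [";".join(p.proteins) for p in psms],
            "sample_id": [p.sample_id for p in psms],
            "score": [p.score for p in psms],
            "is_decoy": [p.is_decoy for p in psms],
            "spectral_count": [p.spectral_count for p in psms],
            "precursor_intensity": [
                np.nan if p.precursor_intensity is None else p.precursor_intensity
                for p in psms
            ],
        }
    )


def write_psm_table(psms: Iterable[PsmRecord] | pd.DataFrame, path: str | Path) -> None:
    df = psms_to_frame(psms).copy()
    df.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# FASTA / lineage / GO


def read_fasta(path: str | Path) -> ProteinCatalog:
    """Read a protein FASTA into a catalog (sequence, length, taxid, host flag).

    Headers may carry ``taxid=<int>`` and ``host=<0|1>`` key=value tags in
    the description; absent tags default to taxid -1 (unassigned) and
    host=False. Duplicate accessions are an error.
    """
    path = Path(path)
    rows = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in rows:
            raise ParseError(f"{path}: duplicate accession {acc!r}")
        tags = dict(
            t.split("=", 1) for t in rec.description.split()[1:] if "=" in t
        )
        seq = str(rec.seq)
        rows[acc] = (seq, len(seq), int(tags.get("taxid", -1)), tags.get("host", "0") == "1")
    if not rows:
        raise ParseError(f"{path}: no FASTA records")
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["sequence", "length", "taxid", "is_host"]
    )
    df.index.name = "accession"
    return ProteinCatalog(proteins=df)


def write_fasta(catalog: ProteinCatalog, path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(row.sequence),
            id=acc,
            description=f"taxid={row.taxid} host={int(row.is_host)}",
        )
        for acc, row in catalog.proteins.iterrows()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_lineage(path: str | Path) -> LineageTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"taxid": int})
    if "taxid" not in df.columns:
        _fail(path, 1, "missing 'taxid' column")
    df = df.set_index("taxid")
    return LineageTable(frame=df)


def write_lineage(lineage: LineageTable, path: str | Path) -> None:
    lineage.frame.to_csv(path, sep="\t", na_rep="")


def read_go_annotations(path: str | Path, catalog: ProteinCatalog | None = None) -> dict[str, set[tuple[str, str]]]:
    """Read accession -> {(GO id, namespace)} from TSV; optionally attach to
    ``catalog.go`` in place."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ["accession", "go_id", "namespace"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        _fail(path, 1, f"missing column(s) {missing}")
    bad = ~df["namespace"].isin(["BP", "MF", "CC"])
    if bad.any():
        _fail(path, int(np.flatnonzero(bad)[0]) + 2, f"invalid namespace {df['namespace'][bad].iloc[0]!r}")
    go: dict[str, set[tuple[str, str]]] = {}
    for acc, go_id, ns in df.itertuples(index=False):
        go.setdefault(acc, set()).add((go_id, ns))
    if catalog is not None:
        catalog.go = go
    return go


def write_go_annotations(go: Mapping[str, set[tuple[str, str]]], path: str | Path) -> None:
    rows = [
        (acc, go_id, ns)
        for acc, terms in sorted(go.items())
        for go_id, ns in sorted(terms)
    ]
    pd.DataFrame(rows, columns=["accession", "go_id", "namespace"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# TMT reporter tables


def read_tmt(path: str | Path) -> TmtBlock:
    """Read one batch's reporter-intensity CSV.

    Layout: first column ``accession``; remaining column headers are
    ``channel:sample`` pairs (e.g. ``126:s07``, ``131:pool``). Empty cells
    are missing.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    sample_map = {}
    channels = []
    for col in df.columns:
        if ":" not in col:
            _fail(path, 1, f"TMT column {col!r} not in channel:sample form")
        ch, sample = col.split(":", 1)
        sample_map[ch] = sample
        channels.append(ch)
    df.columns = channels
    return TmtBlock(batch_id=path.stem, sample_map=sample_map, intensities=df)


def write_tmt(block: TmtBlock, path: str | Path) -> None:
    df = block.intensities.copy()
    df.columns = [f"{ch}:{block.sample_map[ch]}" for ch in df.columns]
    df.to_csv(path, na_rep="")


# ---------------------------------------------------------------------------
# Matrices (features x samples, TSV, missing = empty cell)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "feature"
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="")


def write_provenance(path: str | Path, stage: str, params: Mapping[str, object]) -> None:
    """Record a stage's inputs and parameters as JSON next to its outputs."""
    import metaproteo

    doc = {
        "stage": stage,
        "package": "metaproteo",
        "version": metaproteo.__version__,
        "params": {k: _jsonable(v) for k, v in params.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=str))


def _jsonable(v):
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v


# ---------------------------------------------------------------------------
# BIOM v1 (JSON, sparse, "OTU table")


def write_biom(taxon_table, path: str | Path, generated_by: str = "metaproteo") -> None:
    """Write a taxon x sample relative-abundance table as BIOM v1 JSON.

    Each observation carries its lineage (list of rank names) as ``taxonomy``
    metadata when available. Sparse encoding: [row, col, value] triples.
    """
    values = taxon_table.values_frame if hasattr(taxon_table, "values_frame") else taxon_table
    if values.size == 0:
        raise ValueError("cannot write empty taxon table")
    rows, cols = np.nonzero(np.nan_to_num(values.to_numpy(), nan=0.0))
    data = [
        [int(r), int(c), float(values.iat[r, c])] for r, c in zip(rows, cols)
    ]
    taxonomy = getattr(taxon_table, "taxonomy", None)
    obs = []
    for i, name in enumerate(values.index):
        md = None
        if taxonomy is not None and name in taxonomy:
            md = {"taxonomy": list(taxonomy[name])}
        obs.append({"id": str(name), "metadata": md})
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": generated_by,
        "date": "1970-01-01T00:00:00",
        "rows": obs,
        "columns": [{"id": str(c), "metadata": None} for c in values.columns],
        "matrix_type": "sparse",
        "matrix_element_type": "float",
        "shape": [int(values.shape[0]), int(values.shape[1])],
        "data": data,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_biom(path: str | Path) -> pd.DataFrame:
    doc = json.loads(Path(path).read_text())
    n, m = doc["shape"]
    arr = np.zeros((n, m))
    if doc["matrix_type"] == "sparse":
        for r, c, v in doc["data"]:
            arr[r, c] = v
    else:
        arr = np.asarray(doc["data"], dtype=float)
    return pd.DataFrame(
        arr,
        index=[row["id"] for row in doc["rows"]],
        columns=[col["id"] for col in doc["columns"]],
    )
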