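"""Synthetic metaproteomics experiments with known ground truth.

The generator emulates the structure of a two-diet rat cecal metaproteome
study: two groups of nine animals (digestible starch, animals 7-15, vs
resistant starch, animals 16-24), a host protein fraction on top of a
bacterial community with phylum-to-species lineages, spectral counts drawn
multinomially per sample against a fixed sequencing-style depth budget,
precursor intensities proportional to abundance x protein length with
log-normal noise, missing-not-at-random dropout of low intensities, decoy
PSMs from a down-shifted score distribution, and four TMT batches that
each carry a pooled reference channel.

Everything is driven by one integer seed: identical configs produce
identical tables. Planted effects (protein- or species-level log2 fold
changes applied to the resistant-starch group) are recorded in a
GroundTruth object so downstream estimates can be scored against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    LineageTable,
    ProteinCatalog,
    RANKS,
    TmtBlock,
    write_fasta,
    write_go_annotations,
    write_lineage,
    write_psm_table,
    write_tmt,
)
from .quantify import tryptic_digest

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "SimulationConfigError",
    "simulate_experiment",
    "resimulate_matrices",
    "study_config",
    "write_fixture",
    "default_samples",
    "default_groups",
]

AMINO_ACIDS = "ACDEFGHILMNPQSTVWYKR"
HOST_TAXID = 10116
HOST_LINEAGE = ("Eukaryota", "Chordata", "Mammalia", "Rodentia", "Muridae", "Rattus", "Rattus norvegicus")

# (phylum, class, order, family, genus) templates for the bacterial community
_PHYLA = [
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Ruminococcus"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia"),
    ("Actinobacteria", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium"),
    ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Akkermansiaceae", "Akkermansia"),
    ("Spirochaetes", "Spirochaetia", "Spirochaetales", "Spirochaetaceae", "Treponema"),
]

# Fixed species the community always contains (resistant-starch ecology:
# one amylolytic degrader and two fibrolytic relatives in one family).
FIXED_SPECIES = (
    "Ruminococcus bromii",
    "Ruminococcus albus",
    "Ruminococcus flavefaciens",
)


class SimulationConfigError(ValueError):
    """Invalid simulation configuration."""


def default_samples() -> list[str]:
    return [f"s{a:02d}" for a in range(7, 25)]


def default_groups(n_per_group: int = 9) -> dict[str, str]:
    ds = [f"s{a:02d}" for a in range(7, 7 + n_per_group)]
    rs = [f"s{a:02d}" for a in range(16, 16 + n_per_group)]
    return {**{s: "DS" for s in ds}, **{s: "RS" for s in rs}}


def _default_tmt_batches() -> list[list[str]]:
    return [
        ["s07", "s08", "s16", "s17", "s18"],
        ["s09", "s10", "s11", "s19", "s20"],
        ["s12", "s13", "s21", "s22"],
        ["s14", "s15", "s23", "s24"],
    ]


@dataclass
class SimConfig:
    """Study-design parameters for one simulated experiment.

    Defaults mirror the emulated study: 9 animals per diet group, four TMT
    batches each with a pooled reference, ~16% host proteins. Parameters
    the study never states (host:bacteria mass ratio, abundance spread,
    between-animal taxon dispersion, missingness shape) are free knobs
    with defaults chosen to look like real cecal metaproteomes.
    """

    seed: int
    n_per_group: int = 9
    n_proteins: int = 2000
    host_fraction: float = 0.16
    n_phyla: int = 4
    n_species: int = 20
    depth_per_sample: int = 30_000
    abundance_sigma: float = 2.0  # ln-scale sd of baseline protein abundance
    taxon_sigma: float = 0.5  # ln-scale sd of per-animal, per-taxon factors
    intensity_sigma: float = 0.35  # ln-scale sd of precursor-intensity noise
    host_mass_ratio: float = 0.2  # expected host:bacteria spectral mass
    effect_table: Sequence[tuple[str, float]] = ()
    missing_model: tuple[float, float] | None = (0.2, 1.5)  # (quantile, steepness)
    tmt_batches: Sequence[Sequence[str]] | None = None
    tmt_detect_fraction: float = 0.3
    tmt_host_bias: float = 2.0  # log2 bonus making TMT detection host-biased
    decoy_fraction: float = 0.1
    decoy_score_shift: float = 12.0
    # relative baseline mass per species: the amylolytic resistant-starch
    # degrader is rare before the diet shift; fibrolytic relatives start at
    # the community-average share (they are abundant pre-intervention)
    species_mass_factors: Mapping[str, float] = field(
        default_factory=lambda: {"Ruminococcus bromii": 0.1}
    )
    target_score_mean: float = 35.0
    score_sd: float = 5.0
    outlier_host_multipliers: Mapping[str, float] = field(default_factory=dict)
    psm_level: bool = True

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise SimulationConfigError("n_per_group must be >= 2")
        if self.n_proteins < 1:
            raise SimulationConfigError("n_proteins must be >= 1")
        for name, v in [
            ("host_fraction", self.host_fraction),
            ("decoy_fraction", self.decoy_fraction),
        ]:
            if not 0 <= v <= 1:
                raise SimulationConfigError(f"{name} must be in [0, 1]")
        if self.missing_model is not None and not 0 <= self.missing_model[0] <= 1:
            raise SimulationConfigError("detection-limit quantile must be in [0, 1]")
        if not 1 <= self.n_phyla <= len(_PHYLA):
            raise SimulationConfigError(f"n_phyla must be in [1, {len(_PHYLA)}]")
        if self.n_species < len(FIXED_SPECIES):
            raise SimulationConfigError(f"n_species must be >= {len(FIXED_SPECIES)}")
        batches = self.tmt_batches if self.tmt_batches is not None else _default_tmt_batches()
        seen: set[str] = set()
        for b in batches:
            dup = seen & set(b)
            if dup:
                raise SimulationConfigError(f"sample(s) in more than one TMT batch: {sorted(dup)}")
            seen |= set(b)
        missing = set(self.samples) - seen
        if missing:
            raise SimulationConfigError(f"sample(s) in no TMT batch: {sorted(missing)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load a config from YAML or JSON; the seed is mandatory."""
        import yaml

        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise SimulationConfigError(f"{path}: expected a mapping")
        if "seed" not in doc:
            raise SimulationConfigError(f"{path}: 'seed' is required")
        if "effect_table" in doc:
            doc["effect_table"] = tuple(
                (str(name), float(value)) for name, value in doc["effect_table"]
            )
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise SimulationConfigError(f"{path}: unknown field(s) {sorted(unknown)}")
        return cls(**doc)

    @property
    def samples(self) -> list[str]:
        ds = [f"s{a:02d}" for a in range(7, 7 + self.n_per_group)]
        rs = [f"s{a:02d}" for a in range(16, 16 + self.n_per_group)]
        return ds + rs

    @property
    def groups(self) -> dict[str, str]:
        return default_groups(self.n_per_group)

    @property
    def batches(self) -> list[list[str]]:
        if self.tmt_batches is not None:
            return [list(b) for b in self.tmt_batches]
        if self.n_per_group == 9:
            return _default_tmt_batches()
        # fall back to chunks of <= 5 samples per batch
        samples = self.samples
        return [samples[i : i + 5] for i in range(0, len(samples), 5)]


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    true_log2fc: pd.Series  # per protein, includes inherited species effects
    protein_species: pd.Series  # species name, or "host"
    null_features: list[str]
    host_bacteria_ratio: pd.Series  # per-sample expected spectral-mass ratio
    enriched_go_terms: list[str]
    species_log2fc: dict[str, float]


@dataclass
class SimResult:
    """Everything one simulated experiment produced."""

    config: SimConfig
    catalog: ProteinCatalog
    lineage: LineageTable
    counts: pd.DataFrame  # protein x sample spectral counts
    intensities: pd.DataFrame  # protein x sample precursor intensities (NaN = missing)
    psms: pd.DataFrame | None
    tmt: list[TmtBlock]
    truth: GroundTruth

    @property
    def groups(self) -> dict[str, str]:
        return self.config.groups


# ---------------------------------------------------------------------------
# catalog construction


def _species_pool(config: SimConfig) -> list[tuple[str, tuple[str, ...]]]:
    """(species name, full lineage) for every bacterial species."""
    phyla = _PHYLA[: config.n_phyla]
    pool: list[tuple[str, tuple[str, ...]]] = []
    rum = _PHYLA[0]
    for sp in FIXED_SPECIES:
        pool.append((sp, ("Bacteria", *rum, sp)))
    i = 1
    while len(pool) < config.n_species:
        ph = phyla[(len(pool) - len(FIXED_SPECIES)) % len(phyla)]
        name = f"{ph[4]} sp{i:03d}"
        pool.append((name, ("Bacteria", *ph, name)))
        i += 1
    return pool


def build_lineage(config: SimConfig) -> tuple[LineageTable, dict[str, int]]:
    """Lineage table over all species plus the host; returns name -> taxid."""
    pool = _species_pool(config)
    rows = {}
    taxid_of = {}
    for i, (name, lin) in enumerate(pool):
        taxid = 1000 + i
        taxid_of[name] = taxid
        rows[taxid] = dict(zip(RANKS, lin))
    rows[HOST_TAXID] = dict(zip(RANKS, HOST_LINEAGE))
    taxid_of["host"] = HOST_TAXID
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "taxid"
    return LineageTable(frame=frame), taxid_of


def _aa_probs() -> np.ndarray:
    # K/R placed at ~11% combined so the in-silico digest is nondegenerate
    probs = np.full(len(AMINO_ACIDS), 0.89 / 18)
    probs[AMINO_ACIDS.index("K")] = 0.055
    probs[AMINO_ACIDS.index("R")] = 0.055
    return probs


def _random_sequences(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    letters = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    total = int(np.sum(lengths))
    idx = rng.choice(len(AMINO_ACIDS), size=total, p=_aa_probs())
    blob = letters[idx].tobytes().decode()
    offsets = np.r_[0, np.cumsum(lengths)]
    return [blob[offsets[i] : offsets[i + 1]] for i in range(len(lengths))]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _random_sequences(rng, np.array([length]))[0]


def build_catalog(config: SimConfig, rng: np.random.Generator) -> tuple[ProteinCatalog, LineageTable, pd.Series]:
    """Protein catalog (sequences, lengths, taxids, host flags) plus the
    species assignment of every protein."""
    lineage, taxid_of = build_lineage(config)
    n_host = int(round(config.host_fraction * config.n_proteins))
    n_bact = config.n_proteins - n_host
    species_names = [name for name, _ in _species_pool(config)]
    accs = [f"HOST_{i:05d}" for i in range(n_host)] + [f"MP_{i:05d}" for i in range(n_bact)]
    species = ["host"] * n_host + [
        species_names[i % len(species_names)] for i in range(n_bact)
    ]
    lengths = np.clip(
        np.round(rng.lognormal(math.log(300), 0.4, size=config.n_proteins)),
        60,
        3000,
    ).astype(int)
    seqs = _random_sequences(rng, lengths)
    df = pd.DataFrame(
        {
            "sequence": seqs,
            "length": lengths,
            "taxid": [taxid_of[s] for s in species],
            "is_host": [s == "host" for s in species],
        },
        index=pd.Index(accs, name="accession"),
    )
    return ProteinCatalog(proteins=df), lineage, pd.Series(species, index=accs, name="species")


# ---------------------------------------------------------------------------
# effects and abundances


def _resolve_effects(
    config: SimConfig, accessions: pd.Index, species: pd.Series
) -> tuple[pd.Series, dict[str, float]]:
    lfc = pd.Series(0.0, index=accessions)
    species_lfc: dict[str, float] = {}
    known_species = set(species.unique())
    for name, value in config.effect_table:
        if name in accessions:
            lfc[name] += value
        elif name in known_species:
            lfc[species == name] += value
            species_lfc[name] = species_lfc.get(name, 0.0) + value
        else:
            raise SimulationConfigError(
                f"effect_table references unknown feature or taxon {name!r}"
            )
    return lfc, species_lfc


def _sample_weights(
    config: SimConfig,
    rng: np.random.Generator,
    base: np.ndarray,
    lengths: np.ndarray,
    species: pd.Series,
    lfc: pd.Series,
) -> pd.DataFrame:
    """Per-sample expected spectral mass w = a * taxon factor * effect * L."""
    samples = config.samples
    groups = config.groups
    taxa = species.unique()
    taxon_idx = species.map({t: i for i, t in enumerate(taxa)}).to_numpy()
    eff = np.power(2.0, lfc.to_numpy())
    host_mask = (species == "host").to_numpy()
    cols = {}
    for s in samples:
        f = rng.lognormal(0.0, config.taxon_sigma, size=len(taxa))
        w = base * f[taxon_idx]
        if groups[s] == "RS":
            w = w * eff
        mult = config.outlier_host_multipliers.get(s)
        if mult is not None:
            w = np.where(host_mask, w * mult, w)
        cols[s] = w * lengths
    return pd.DataFrame(cols, index=species.index)


def simulate_experiment(config: SimConfig) -> SimResult:
    """Run the full generator; identical config (incl. seed) => identical output."""
    rng = np.random.default_rng(config.seed)
    catalog, lineage, species = build_catalog(config, rng)
    lengths = catalog.lengths.to_numpy().astype(float)
    lfc, species_lfc = _resolve_effects(config, catalog.accessions, species)

    base = rng.lognormal(0.0, config.abundance_sigma, size=config.n_proteins)
    if config.species_mass_factors:
        unknown = set(config.species_mass_factors) - set(species.unique())
        if unknown:
            raise SimulationConfigError(
                f"species_mass_factors references unknown species {sorted(unknown)}"
            )
        base = base * species.map(
            lambda sp: config.species_mass_factors.get(sp, 1.0)
        ).to_numpy()
    # scale host proteins so the expected host:bacteria spectral mass ratio
    # matches the configured value
    host_mask = catalog.is_host.to_numpy()
    if host_mask.any() and (~host_mask).any():
        host_mass = float((base * lengths)[host_mask].sum())
        bact_mass = float((base * lengths)[~host_mask].sum())
        base = np.where(
            host_mask, base * config.host_mass_ratio * bact_mass / host_mass, base
        )

    weights = _sample_weights(config, rng, base, lengths, species, lfc)
    counts = _draw_counts(config, rng, weights)
    intensities = _draw_intensities(config, rng, weights)
    tmt = _draw_tmt(config, rng, weights, host_mask)
    psms = _draw_psms(config, rng, catalog, counts, intensities) if config.psm_level else None

    host_mass_s = weights.loc[host_mask].sum(axis=0)
    bact_mass_s = weights.loc[~host_mask].sum(axis=0)
    truth = GroundTruth(
        true_log2fc=lfc,
        protein_species=species,
        null_features=list(lfc.index[lfc == 0.0]),
        host_bacteria_ratio=(host_mass_s / bact_mass_s).rename("host_bacteria_ratio"),
        enriched_go_terms=[],
        species_log2fc=species_lfc,
    )
    catalog.go = _draw_go(config, rng, catalog, lfc, truth)
    return SimResult(
        config=config,
        catalog=catalog,
        lineage=lineage,
        counts=counts,
        intensities=intensities,
        psms=psms,
        tmt=tmt,
        truth=truth,
    )


def _draw_counts(config, rng, weights: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    for s in weights.columns:
        p = weights[s].to_numpy()
        cols[s] = rng.multinomial(config.depth_per_sample, p / p.sum())
    return pd.DataFrame(cols, index=weights.index)


def _draw_intensities(config, rng, weights: pd.DataFrame) -> pd.DataFrame:
    noise = rng.lognormal(0.0, config.intensity_sigma, size=weights.shape)
    inten = weights.to_numpy() * noise * 1e4 / weights.to_numpy().mean()
    inten = pd.DataFrame(inten, index=weights.index, columns=weights.columns)
    if config.missing_model is None:
        return inten
    quantile, steepness = config.missing_model
    logi = np.log2(inten.to_numpy())
    threshold = np.quantile(logi, quantile)
    detect_p = 1.0 / (1.0 + np.exp(-steepness * (logi - threshold)))
    observed = rng.uniform(size=inten.shape) < detect_p
    return inten.where(observed)


def _draw_tmt(config, rng, weights: pd.DataFrame, host_mask: np.ndarray) -> list[TmtBlock]:
    channels = ["126", "127", "128", "129", "130", "131"]
    pool_base = weights.mean(axis=1)
    # detection biased toward abundant and host proteins
    score = np.log2(pool_base.to_numpy()) + config.tmt_host_bias * host_mask
    n_detect = max(1, int(round(config.tmt_detect_fraction * len(weights))))
    detected = weights.index[np.argsort(score)[::-1][:n_detect]]
    blocks = []
    for b, samples in enumerate(config.batches, start=1):
        if len(samples) + 1 > len(channels):
            raise SimulationConfigError(f"batch {b} has too many samples for TMT6")
        cols = {}
        sample_map = {}
        for ch, s in zip(channels, samples):
            noise = rng.lognormal(0.0, 0.25, size=n_detect)
            cols[ch] = weights.loc[detected, s].to_numpy() * noise
            sample_map[ch] = s
        pool_ch = channels[len(samples)]
        cols[pool_ch] = pool_base.loc[detected].to_numpy() * rng.lognormal(0.0, 0.25, size=n_detect)
        sample_map[pool_ch] = TmtBlock.POOL
        blocks.append(
            TmtBlock(
                batch_id=f"tmt_batch{b}",
                sample_map=sample_map,
                intensities=pd.DataFrame(cols, index=detected),
            )
        )
    return blocks


def _draw_psms(
    config, rng, catalog: ProteinCatalog, counts: pd.DataFrame, intensities: pd.DataFrame
) -> pd.DataFrame:
    peptides_of = {
        acc: [p for p in tryptic_digest(seq) if 7 <= len(p) <= 30] or [seq[:15]]
        for acc, seq in catalog.proteins["sequence"].items()
    }
    rows: list[tuple] = []
    count_arr = counts.to_numpy()
    inten_arr = intensities.to_numpy()
    accs = list(counts.index)
    samples = list(counts.columns)
    for i, acc in enumerate(accs):
        peps = peptides_of[acc]
        for j, s in enumerate(samples):
            c = int(count_arr[i, j])
            if c == 0:
                continue
            k = min(len(peps), max(1, 1 + rng.poisson(1.5)))
            chosen = rng.choice(len(peps), size=k, replace=False)
            shares = rng.multinomial(c, np.full(k, 1.0 / k))
            inten = inten_arr[i, j]
            for pi, share in zip(chosen, shares):
                if share == 0:
                    continue
                frac = share / c
                rows.append(
                    (
                        peps[pi],
                        acc,
                        s,
                        float(rng.normal(config.target_score_mean, config.score_sd)),
                        False,
                        int(share),
                        float(inten * frac) if np.isfinite(inten) else np.nan,
                    )
                )
    n_decoys = int(round(config.decoy_fraction * len(rows)))
    for d in range(n_decoys):
        length = int(rng.integers(8, 21))
        rows.append(
            (
                _random_sequence(rng, length),
                f"DECOY_{d:05d}",
                samples[d % len(samples)],
                float(rng.normal(config.target_score_mean - config.decoy_score_shift, config.score_sd)),
                True,
                1,
                np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peptide",
            "proteins",
            "sample_id",
            "score",
            "is_decoy",
            "spectral_count",
            "precursor_intensity",
        ],
    )


def _draw_go(
    config, rng, catalog: ProteinCatalog, lfc: pd.Series, truth: GroundTruth
) -> dict[str, set[tuple[str, str]]]:
    """Random flat GO annotation, with terms planted on effect proteins."""
    n_per_ns = 25
    terms = {
        ns: [f"GO:{1000000 + 100 * k + i:07d}" for i in range(n_per_ns)]
        for k, ns in enumerate(("BP", "MF", "CC"))
    }
    accessions = list(catalog.accessions)
    go: dict[str, set[tuple[str, str]]] = {acc: set() for acc in accessions}
    for ns, ids in terms.items():
        # background: each (protein, term) pair annotated independently at
        # 1/n_per_ns, i.e. ~1 term per namespace per protein
        mask = rng.uniform(size=(len(accessions), n_per_ns)) < 1.0 / n_per_ns
        for i, j in zip(*np.nonzero(mask)):
            go[accessions[i]].add((ids[j], ns))
    up = lfc.index[lfc > 0]
    down = lfc.index[lfc < 0]
    planted = []
    for direction, accs, ns in (("up", up, "BP"), ("down", down, "MF")):
        if len(accs) == 0:
            continue
        term = f"GO:{2000000 if direction == 'up' else 2000001:07d}"
        planted.append(term)
        for acc in accs:
            if rng.uniform() < 0.6:
                go[acc].add((term, ns))
        background = lfc.index[lfc == 0]
        for acc in background:
            if rng.uniform() < 0.03:
                go[acc].add((term, ns))
    truth.enriched_go_terms = planted
    return go


def resimulate_matrices(config: SimConfig, seed: int) -> SimResult:
    """Re-draw abundances/counts/intensities under a new seed (same design).

    Convenience for replicate studies: equivalent to
    ``simulate_experiment(replace(config, seed=seed, psm_level=False))``.
    """
    return simulate_experiment(replace(config, seed=seed, psm_level=False))


# Rare saccharolytic species that feed on resistant-starch degradation
# products: near the detection limit on the digestible-starch diet, they
# rise severalfold with resistant starch (the species-level mechanism
# behind the alpha-diversity increase).
RS_UTILIZERS = (
    "Bacteroides sp002",
    "Bifidobacterium sp004",
    "Ruminococcus sp005",
    "Bacteroides sp006",
    "Bifidobacterium sp008",
    "Ruminococcus sp009",
)


def study_config(
    seed: int,
    n_proteins: int = 2000,
    depth_per_sample: int = 30_000,
    n_protein_effects: int = 100,
    psm_level: bool = True,
) -> SimConfig:
    """The emulated study scenario, fully specified by one seed.

    Plants the community shifts the diet contrast produces — the amylolytic
    degrader up ~12x, two fibrolytic relatives down 20x and 10x, a guild of
    rare starch-product utilizers up ~5x from near the detection limit —
    plus ``n_protein_effects`` random protein-level effects of |log2FC| = 2
    (half up, half down) and two samples with extreme host:bacteria ratios
    (one per diet group) destined for QC exclusion.
    """
    rng = np.random.default_rng(seed)
    n_host = int(round(0.16 * n_proteins))
    host_accs = [f"HOST_{i:05d}" for i in range(n_host)]
    bact_accs = [f"MP_{i:05d}" for i in range(n_proteins - n_host)]
    # stratified like the real contrast: host effects mostly reductions,
    # bacterial effects mostly increases
    n_host_eff = int(round(0.3 * n_protein_effects))
    chosen_host = rng.choice(host_accs, size=n_host_eff, replace=False)
    chosen_bact = rng.choice(bact_accs, size=n_protein_effects - n_host_eff, replace=False)
    effects: list[tuple[str, float]] = []
    effects += [(a, -2.0) for a in chosen_host[: (2 * n_host_eff) // 3]]
    effects += [(a, 2.0) for a in chosen_host[(2 * n_host_eff) // 3 :]]
    n_bact_up = (2 * len(chosen_bact)) // 3
    effects += [(a, 2.0) for a in chosen_bact[:n_bact_up]]
    effects += [(a, -2.0) for a in chosen_bact[n_bact_up:]]
    effects += [
        ("Ruminococcus bromii", math.log2(12)),
        ("Ruminococcus albus", -math.log2(20)),
        ("Ruminococcus flavefaciens", -math.log2(10)),
    ]
    effects += [(sp, math.log2(5)) for sp in RS_UTILIZERS]
    # Bacteroidetes expansion with resistant starch (phylum-ratio shift)
    effects += [("Bacteroides sp010", 1.0), ("Bacteroides sp014", 1.0)]
    mass_factors = {"Ruminococcus bromii": 0.1}
    mass_factors.update({sp: 0.005 for sp in RS_UTILIZERS})
    return SimConfig(
        seed=seed,
        n_proteins=n_proteins,
        n_species=40,
        depth_per_sample=depth_per_sample,
        effect_table=tuple(effects),
        species_mass_factors=mass_factors,
        # the excluded samples in the emulated study were grossly degraded:
        # their spectra are ~90% host protein
        outlier_host_multipliers={"s09": 150.0, "s21": 200.0},
        psm_level=psm_level,
    )


# ---------------------------------------------------------------------------
# fixture files


def write_fixture(sim: SimResult, dir_path: str | Path) -> list[Path]:
    """Write the simulated experiment as the pipeline's canonical file set.

    Emits psms.tsv, proteins.fasta, lineage.tsv, go_annotations.tsv,
    truth.tsv, samples.tsv and one tmt_batchN.csv per batch; all re-readable
    by the io module.
    """
    if sim.psms is None:
        raise ValueError("fixture requires a PSM-level simulation (psm_level=True)")
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    paths = []

    p = dir_path / "psms.tsv"
    write_psm_table(sim.psms, p)
    paths.append(p)

    p = dir_path / "proteins.fasta"
    write_fasta(sim.catalog, p)
    paths.append(p)

    p = dir_path / "lineage.tsv"
    write_lineage(sim.lineage, p)
    paths.append(p)

    p = dir_path / "go_annotations.tsv"
    write_go_annotations(sim.catalog.go, p)
    paths.append(p)

    p = dir_path / "truth.tsv"
    truth_df = pd.DataFrame(
        {
            "true_log2fc": sim.truth.true_log2fc,
            "species": sim.truth.protein_species,
        }
    )
    truth_df.index.name = "accession"
    truth_df.to_csv(p, sep="\t")
    paths.append(p)

    p = dir_path / "samples.tsv"
    pd.Series(sim.groups, name="group").rename_axis("sample_id").to_csv(p, sep="\t")
    paths.append(p)

    for block in sim.tmt:
        p = dir_path / f"{block.batch_id}.csv"
        write_tmt(block, p)
        paths.append(p)
    return paths
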