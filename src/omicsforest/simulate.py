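"""Synthetic backcross studies with planted multi-omics architecture.

Emulates a diploid backcross mapping population: 12 linkage groups of
evenly spaced markers, two genotype classes per marker (coded 0/1),
recombination along each group following the Haldane map function
(no interference), and omics layers built on top of the genotypes —
cis- and trans-regulated transcripts, metabolites chained downstream of
transcripts, proteins correlated with transcripts, and large blocks of
pure-noise features. The planted architecture is recorded as ground truth
so every downstream stage can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datasets import (
    LAYER_PREFIXES,
    UNKNOWN_GROUP,
    GeneticMap,
    GenotypeMatrix,
    OmicsDataset,
)

__all__ = [
    "FeatureSpec",
    "PathwayChain",
    "Architecture",
    "SyntheticStudy",
    "simulate_map",
    "simulate_backcross",
    "simulate_study",
    "default_architecture",
    "write_study_bundle",
    "haldane_recombination_fraction",
]


def haldane_recombination_fraction(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction r = (1 - exp(-2d/100)) / 2 for distance d in cM."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0)) / 2.0


# ---------------------------------------------------------------------------
# architecture description

@dataclass(frozen=True)
class FeatureSpec:
    """One genetically driven feature.

    ``effect`` is the mean shift between the two genotype classes of the
    driver marker, in the feature's intensity units; ``noise_sd`` the
    residual Gaussian standard deviation.
    """

    feature_id: str
    layer: str
    driver_marker: str
    effect: float
    noise_sd: float


@dataclass(frozen=True)
class PathwayChain:
    """Ordered features where each is a noisy linear function of its
    predecessor; the first link's predecessor is ``source_feature`` (an
    already-defined feature, typically a cis transcript)."""

    source_feature: str
    links: tuple  # of (feature_id, layer, slope, noise_sd)


@dataclass
class Architecture:
    """Planted genetic architecture of a synthetic study."""

    n_individuals: int
    trait_qtls: list[tuple[str, float]] = field(default_factory=list)  # (marker, effect)
    #: trait contributions routed through molecular features (the
    #: genotype -> expression -> trait causal chain): (feature_id, coefficient)
    trait_feature_effects: list[tuple[str, float]] = field(default_factory=list)
    cis_features: list[FeatureSpec] = field(default_factory=list)
    trans_features: list[FeatureSpec] = field(default_factory=list)
    pathway_chains: list[PathwayChain] = field(default_factory=list)
    n_noise_per_layer: dict[str, int] = field(default_factory=dict)
    noise_sd_per_layer: dict[str, float] = field(default_factory=dict)
    trait_noise_sd: float = 1.0
    trait_name: str = "trait"
    annotation_unknown_rate: float = 0.1
    seed: int = 0

    def validate(self, gmap: GeneticMap) -> None:
        markers = set(gmap.marker_ids)
        for marker, effect in self.trait_qtls:
            if marker not in markers:
                raise ValueError(f"trait QTL driver {marker!r} not in map")
            if not np.isfinite(effect):
                raise ValueError("trait QTL effect must be finite")
        for spec in [*self.cis_features, *self.trans_features]:
            if spec.driver_marker not in markers:
                raise ValueError(f"driver marker {spec.driver_marker!r} not in map")
            if not np.isfinite(spec.effect):
                raise ValueError(f"effect of {spec.feature_id!r} must be finite")
            if spec.noise_sd <= 0:
                raise ValueError(f"noise sd of {spec.feature_id!r} must be > 0")
        if self.trait_noise_sd <= 0:
            raise ValueError("trait_noise_sd must be > 0")

    def planted_trait_groups(self, gmap: GeneticMap) -> set[int]:
        """Linkage groups genetically driving the trait: driver groups of
        direct marker QTLs plus driver groups of features the trait is
        routed through."""
        groups = {gmap.group_of(m) for m, _ in self.trait_qtls}
        drivers = {s.feature_id: s.driver_marker
                   for s in [*self.cis_features, *self.trans_features]}
        for fid, _ in self.trait_feature_effects:
            if fid in drivers:
                groups.add(gmap.group_of(drivers[fid]))
        return groups

    def planted_feature_ids(self) -> list[str]:
        ids = [s.feature_id for s in self.cis_features]
        ids += [s.feature_id for s in self.trans_features]
        for chain in self.pathway_chains:
            ids += [link[0] for link in chain.links]
        return ids


@dataclass
class SyntheticStudy:
    """A generated study bundle plus the architecture used to build it."""

    genotypes: GenotypeMatrix
    gmap: GeneticMap
    traits: pd.DataFrame
    layers: list[OmicsDataset]
    annotation: pd.DataFrame
    truth: Architecture

    def layer_by_name(self, name: str) -> OmicsDataset:
        for layer in self.layers:
            if layer.layer == name:
                return layer
        raise KeyError(f"no layer named {name!r}")


# ---------------------------------------------------------------------------
# simulation

def simulate_map(
    n_groups: int, markers_per_group: int, spacing: float, seed: int | None = None
) -> GeneticMap:
    """Evenly spaced grid map: ``markers_per_group`` markers per linkage
    group at 0, spacing, 2*spacing, ... cM. The layout is deterministic;
    ``seed`` is accepted for signature symmetry with the other simulators.
    """
    if n_groups < 1 or markers_per_group < 2 or spacing <= 0:
        raise ValueError("need n_groups >= 1, markers_per_group >= 2, spacing > 0")
    rows = []
    for g in range(1, n_groups + 1):
        for i in range(markers_per_group):
            rows.append((f"M{g}_{i + 1}", g, i * float(spacing)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker_id", "linkage_group", "position_cM"]))


def simulate_backcross(gmap: GeneticMap, n: int, seed: int = 0) -> GenotypeMatrix:
    """Simulate n backcross individuals along the map.

    Per individual and linkage group the genotype is a Markov chain: the
    first marker is 0/1 with probability 1/2, and each subsequent marker
    flips class with the Haldane recombination fraction of the inter-marker
    distance. Linkage groups are independent.
    """
    if gmap.n_markers == 0:
        raise ValueError("empty genetic map")
    if n < 2:
        raise ValueError("need n >= 2 individuals")
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    for group in gmap.groups:
        sub = gmap.markers_in_group(group)
        pos = sub["position_cM"].to_numpy(dtype=float)
        ids = list(sub["marker_id"])
        state = (rng.random(n) < 0.5).astype(np.int8)
        columns[ids[0]] = state.copy()
        for k in range(1, len(ids)):
            r = haldane_recombination_fraction(pos[k] - pos[k - 1])
            flip = rng.random(n) < r
            state = np.where(flip, 1 - state, state).astype(np.int8)
            columns[ids[k]] = state.copy()
    values = pd.DataFrame(
        {m: columns[m] for m in gmap.marker_ids},
        index=[f"BC{i + 1:03d}" for i in range(n)],
        dtype=float,
    )
    return GenotypeMatrix(values)


def _genotype_column(genotypes: GenotypeMatrix, marker: str) -> np.ndarray:
    if marker not in genotypes.values.columns:
        raise ValueError(f"unknown driver marker {marker!r}")
    return genotypes.values[marker].to_numpy(dtype=float)


def simulate_study(
    gmap: GeneticMap, genotypes: GenotypeMatrix, arch: Architecture
) -> SyntheticStudy:
    """Build trait, omics layers, annotation and ground truth on top of a
    genotype matrix.

    The trait is the sum of its marker-QTL effects times the driver
    genotypes, plus any trait-feature effects times the corresponding
    feature values (genotype -> molecular feature -> trait chains), plus
    Gaussian noise. Cis/trans features come from their driver genotypes;
    pathway-chain elements are noisy linear functions of their
    predecessor; noise features are pure Gaussian. Fully reproducible from
    ``arch.seed``.
    """
    arch.validate(gmap)
    n = len(genotypes.samples)
    if arch.n_individuals != n:
        raise ValueError(
            f"architecture expects {arch.n_individuals} individuals, genotypes have {n}"
        )
    rng = np.random.default_rng(arch.seed)
    samples = genotypes.samples

    feature_values: dict[str, dict[str, np.ndarray]] = {}  # layer -> {fid: values}
    annotation_rows: list[tuple[str, object, float]] = []

    def add_feature(layer: str, fid: str, vals: np.ndarray) -> None:
        bucket = feature_values.setdefault(layer, {})
        if fid in bucket:
            raise ValueError(f"duplicate feature id {fid!r}")
        bucket[fid] = vals

    groups = gmap.groups
    for spec in arch.cis_features:
        g = _genotype_column(genotypes, spec.driver_marker)
        add_feature(spec.layer, spec.feature_id, spec.effect * g + rng.normal(0, spec.noise_sd, n))
        drv_group = gmap.group_of(spec.driver_marker)
        if rng.random() < arch.annotation_unknown_rate:
            annotation_rows.append((spec.feature_id, UNKNOWN_GROUP, np.nan))
        else:
            annotation_rows.append(
                (spec.feature_id, drv_group, gmap.position_of(spec.driver_marker))
            )
    for spec in arch.trans_features:
        g = _genotype_column(genotypes, spec.driver_marker)
        add_feature(spec.layer, spec.feature_id, spec.effect * g + rng.normal(0, spec.noise_sd, n))
        drv_group = gmap.group_of(spec.driver_marker)
        if rng.random() < arch.annotation_unknown_rate:
            annotation_rows.append((spec.feature_id, UNKNOWN_GROUP, np.nan))
        else:
            others = [g2 for g2 in groups if g2 != drv_group] or [drv_group]
            annotation_rows.append((spec.feature_id, int(rng.choice(others)), 0.0))

    all_defined = {fid: (layer, vals) for layer, d in feature_values.items() for fid, vals in d.items()}
    for chain in arch.pathway_chains:
        if chain.source_feature not in all_defined:
            raise ValueError(f"chain source {chain.source_feature!r} is not a defined feature")
        prev = all_defined[chain.source_feature][1]
        for fid, layer, slope, noise_sd in chain.links:
            if noise_sd <= 0:
                raise ValueError(f"noise sd of chain link {fid!r} must be > 0")
            vals = slope * prev + rng.normal(0, noise_sd, n)
            add_feature(layer, fid, vals)
            all_defined[fid] = (layer, vals)
            annotation_rows.append((fid, UNKNOWN_GROUP, np.nan))
            prev = vals

    for layer, count in arch.n_noise_per_layer.items():
        prefix = LAYER_PREFIXES.get(layer, layer.capitalize())
        sd = arch.noise_sd_per_layer.get(layer, 1.0)
        start = len(feature_values.get(layer, {})) + 1
        for k in range(count):
            fid = f"{prefix}_n{start + k:05d}"
            add_feature(layer, fid, rng.normal(0.0, sd, n))
            annotation_rows.append((fid, int(rng.choice(groups)), float(rng.random() * 100)))

    trait = np.zeros(n)
    for marker, effect in arch.trait_qtls:
        trait = trait + effect * _genotype_column(genotypes, marker)
    for fid, coef in arch.trait_feature_effects:
        if fid not in all_defined:
            raise ValueError(f"trait feature effect refers to unknown feature {fid!r}")
        trait = trait + coef * all_defined[fid][1]
    trait = trait + rng.normal(0.0, arch.trait_noise_sd, size=n)
    traits = pd.DataFrame({arch.trait_name: trait}, index=samples)

    layers = [
        OmicsDataset(layer, pd.DataFrame(d, index=samples).T)
        for layer, d in feature_values.items()
    ]
    annotation = pd.DataFrame(
        annotation_rows, columns=["feature_id", "linkage_group", "position_cM"]
    )
    return SyntheticStudy(genotypes, gmap, traits, layers, annotation, arch)


def default_architecture(seed: int = 0) -> Architecture:
    """Architecture emulating the scale of a potato backcross quality-trait
    study: 96 individuals, twelve chromosomes, a trait sitting downstream
    of three cis-regulated transcripts (genotype -> expression -> trait)
    plus one direct QTL whose mediator is unmeasured, a trans-regulated
    transcript, metabolites downstream of a transcript, a protein
    correlated with a transcript, and noise blocks in the 10^2-10^3 range
    per layer (the transcript layer largest, as in microarray data).

    Designed for a map from ``simulate_map(12, 10, 10.0)``.
    """
    cis = [
        FeatureSpec("Gene_1", "gene", "M2_5", 2.0, 1.0),
        FeatureSpec("Gene_2", "gene", "M3_4", 2.0, 1.0),
        FeatureSpec("Gene_3", "gene", "M8_6", 1.6, 1.0),
    ]
    trans = [FeatureSpec("Gene_4", "gene", "M2_5", 1.2, 1.0)]
    chains = [
        PathwayChain("Gene_1", (("LC_1", "lc", 0.9, 0.6), ("GC_1", "gc", 0.8, 0.6))),
        PathwayChain("Gene_2", (("Pro_1", "protein", 0.9, 0.6),)),
    ]
    return Architecture(
        n_individuals=96,
        trait_qtls=[("M11_3", 0.6)],
        trait_feature_effects=[("Gene_1", 0.8), ("Gene_2", 0.7), ("Gene_3", 0.6)],
        cis_features=cis,
        trans_features=trans,
        pathway_chains=chains,
        n_noise_per_layer={"gene": 2000, "lc": 230, "gc": 135, "protein": 150},
        trait_noise_sd=1.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# bundle writer

def write_study_bundle(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the study as the standard TSV bundle plus a truth JSON.

    Layout: ``<layer>.tsv`` per omics layer (rows = features, first column
    ``feature_id``, remaining columns sample IDs), ``traits.tsv`` (rows =
    samples), ``genotypes.tsv`` (rows = samples, entries 0/1/NA),
    ``map.tsv``, ``annotation.tsv`` and ``truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for layer in study.layers:
        p = out / f"{layer.layer}.tsv"
        layer.values.to_csv(p, sep="\t", index_label="feature_id")
        paths[f"layer:{layer.layer}"] = p
    p = out / "traits.tsv"
    study.traits.to_csv(p, sep="\t", index_label="sample_id")
    paths["traits"] = p
    p = out / "genotypes.tsv"
    study.genotypes.values.to_csv(p, sep="\t", index_label="sample_id", na_rep="NA")
    paths["genotypes"] = p
    p = out / "map.tsv"
    study.gmap.table.to_csv(p, sep="\t", index=False)
    paths["map"] = p
    p = out / "annotation.tsv"
    study.annotation.to_csv(p, sep="\t", index=False)
    paths["annotation"] = p

    truth = asdict(study.truth)
    truth["pathway_chains"] = [
        {"source_feature": c.source_feature, "links": [list(l) for l in c.links]}
        for c in study.truth.pathway_chains
    ]
    p = out / "truth.json"
    p.write_text(json.dumps(truth, indent=2, default=str))
    paths["truth"] = p
    return paths
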