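"""Study-bundle readers/writers, sample alignment, and analysis config.

The on-disk bundle is plain TSV: one file per omics layer (rows =
features, first column ``feature_id``, remaining columns = sample IDs), a
trait table (rows = samples), an optional genotype matrix (rows = samples,
entries 0/1/NA) with its genetic map, and an optional physical annotation
of features. The synthetic generator writes exactly this layout.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .datasets import (
    AlignmentError,
    GeneticMap,
    GenotypeMatrix,
    OmicsDataset,
    StudyBundle,
)
from .rf import RFParams

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "read_omics_tsv",
    "read_trait_tsv",
    "read_genotypes_tsv",
    "read_map_tsv",
    "read_annotation_tsv",
    "load_study",
    "align_samples",
]


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc


def read_omics_tsv(path: str | Path, layer: str | None = None) -> OmicsDataset:
    df = _read_tsv(path, index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicate feature ID {list(dupes)[:5]}")
    df.index.name = None
    name = layer or Path(path).stem
    return OmicsDataset(name, df.astype(float))


def read_trait_tsv(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs")
    df.index = df.index.astype(str)
    df.index.name = None
    return df.astype(float)


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = _read_tsv(path, index_col=0, na_values=["NA"])
    df.index.name = None
    return GenotypeMatrix(df.astype(float))


def read_map_tsv(path: str | Path) -> GeneticMap:
    return GeneticMap(_read_tsv(path))


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    if "feature_id" not in df.columns or "linkage_group" not in df.columns:
        raise ValueError(f"{path}: annotation needs feature_id and linkage_group columns")
    return df


def load_study(
    layer_paths: Mapping[str, str | Path],
    trait_path: str | Path,
    genotype_path: str | Path | None = None,
    map_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
) -> StudyBundle:
    """Load and validate a study bundle.

    ``layer_paths`` maps layer names (gene/lc/gc/protein/...) to TSV files.
    Samples present in a layer but absent from the trait table are handled
    later by :func:`align_samples`; duplicate feature IDs are rejected here.
    """
    layers = [read_omics_tsv(p, layer=name) for name, p in layer_paths.items()]
    traits = read_trait_tsv(trait_path)
    genotypes = read_genotypes_tsv(genotype_path) if genotype_path else None
    gmap = read_map_tsv(map_path) if map_path else None
    annotation = read_annotation_tsv(annotation_path) if annotation_path else None
    bundle = StudyBundle(layers, traits, genotypes, gmap, annotation)
    logger.info(
        "loaded study: %d layers (%s), %d trait samples, genetics=%s",
        len(layers), ", ".join(l.layer for l in layers), len(traits), bundle.has_genetics,
    )
    return bundle


def load_study_dir(directory: str | Path, layers: Sequence[str] | None = None) -> StudyBundle:
    """Load a bundle from a directory in the generator's standard layout."""
    d = Path(directory)
    reserved = {"traits", "genotypes", "map", "annotation", "truth"}
    if layers is None:
        layers = sorted(
            p.stem for p in d.glob("*.tsv") if p.stem not in reserved
        )
    layer_paths = {name: d / f"{name}.tsv" for name in layers}
    return load_study(
        layer_paths,
        d / "traits.tsv",
        genotype_path=(d / "genotypes.tsv") if (d / "genotypes.tsv").exists() else None,
        map_path=(d / "map.tsv") if (d / "map.tsv").exists() else None,
        annotation_path=(d / "annotation.tsv") if (d / "annotation.tsv").exists() else None,
    )


def align_samples(bundle: StudyBundle, trait: str) -> StudyBundle:
    """Restrict every matrix to the sorted intersection of sample IDs.

    Samples missing the requested trait value are dropped. Raises when the
    intersection has fewer than 10 samples.
    """
    if trait not in bundle.traits.columns:
        raise KeyError(f"trait {trait!r} not in trait table")
    shared = set(bundle.traits.index[bundle.traits[trait].notna()])
    for layer in bundle.layers:
        shared &= set(layer.samples)
    if bundle.genotypes is not None:
        shared &= set(bundle.genotypes.samples)
    if len(shared) < 10:
        raise AlignmentError(f"sample intersection has only {len(shared)} samples")
    order = sorted(shared)
    dropped = set(bundle.traits.index) - shared
    if dropped:
        logger.warning("dropping %d samples outside the intersection", len(dropped))
    logger.info("aligned on %d shared samples", len(order))
    layers = [OmicsDataset(l.layer, l.values[order]) for l in bundle.layers]
    traits = bundle.traits.loc[order]
    genotypes = (
        GenotypeMatrix(bundle.genotypes.values.loc[order])
        if bundle.genotypes is not None
        else None
    )
    return StudyBundle(layers, traits, genotypes, bundle.gmap, bundle.annotation)


@dataclass
class AnalysisConfig:
    """Everything one end-to-end run needs; round-trips through YAML."""

    trait: str = "trait"
    rf: RFParams = field(default_factory=RFParams)
    n_perm: int = 1000
    alpha_model: float = 0.001
    alpha_feature: float = 0.001
    per_feature_null: bool = False
    qtl_alpha: float = 0.05
    qtl_n_perm: int = 1000
    penalty_criterion: str = "ebic"
    penalty_grid: Optional[list[float]] = None
    seed: int = 0
    out_dir: str = "results"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "rf" in payload and isinstance(payload["rf"], dict):
            payload["rf"] = RFParams(**payload["rf"])
        return cls(**payload)

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]
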