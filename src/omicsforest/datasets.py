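"""Core data containers shared across the pipeline.

The pipeline operates on a *study bundle*: one or more omics layers
(feature-by-sample intensity matrices), a trait table, and — when the study
is a mapping population — a backcross genotype matrix with its genetic map
and an optional physical annotation of features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

#: Feature-ID prefix per omics layer, following the field's nomenclature
#: (Gene_X for transcripts, LC_X / GC_X for LC-MS / GC-MS centrotypes,
#: Pro_X for 2D-DIGE protein spots).
LAYER_PREFIXES = {"gene": "Gene", "lc": "LC", "gc": "GC", "protein": "Pro"}

#: Label used for features whose physical map position is unknown.
UNKNOWN_GROUP = "unknown"


class AlignmentError(ValueError):
    """Samples of two components cannot be aligned."""


class DegenerateInputError(ValueError):
    """Input is constant or otherwise carries no usable variation."""


@dataclass
class OmicsDataset:
    """One omics layer: a feature x sample matrix of processed intensities.

    Parameters
    ----------
    layer
        Layer label, one of ``gene``, ``lc``, ``gc``, ``protein`` or a free
        label such as ``combined``.
    values
        DataFrame with features as rows (index = feature IDs) and samples as
        columns (sample IDs). Missing intensities are NaN.
    """

    layer: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature IDs in layer {self.layer!r}: {list(dupes)[:5]}")
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def to_sample_matrix(self) -> pd.DataFrame:
        """Samples x features orientation used by the learners."""
        return self.values.T

    def restrict(self, feature_ids: Iterable[str]) -> "OmicsDataset":
        ids = list(feature_ids)
        missing = set(ids) - set(self.values.index)
        if missing:
            raise KeyError(f"features not in layer {self.layer!r}: {sorted(missing)[:5]}")
        return OmicsDataset(self.layer, self.values.loc[ids])


@dataclass
class GeneticMap:
    """Ordered marker list with linkage groups and centiMorgan positions."""

    table: pd.DataFrame  # columns: marker_id, linkage_group, position_cM

    def __post_init__(self) -> None:
        required = {"marker_id", "linkage_group", "position_cM"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"genetic map needs columns {sorted(required)}")
        self.table = self.table.reset_index(drop=True)
        if self.table["marker_id"].duplicated().any():
            raise ValueError("duplicate marker IDs in genetic map")
        if (self.table["position_cM"] < 0).any():
            raise ValueError("negative cM positions in genetic map")
        for _, sub in self.table.groupby("linkage_group"):
            if not sub["position_cM"].is_monotonic_increasing:
                raise ValueError("positions must be non-decreasing within a linkage group")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table["marker_id"])

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def groups(self) -> list[int]:
        return sorted(self.table["linkage_group"].unique())

    def group_of(self, marker_id: str) -> int:
        row = self.table.loc[self.table["marker_id"] == marker_id]
        if row.empty:
            raise KeyError(f"marker {marker_id!r} not in map")
        return int(row["linkage_group"].iloc[0])

    def position_of(self, marker_id: str) -> float:
        row = self.table.loc[self.table["marker_id"] == marker_id]
        if row.empty:
            raise KeyError(f"marker {marker_id!r} not in map")
        return float(row["position_cM"].iloc[0])

    def markers_in_group(self, group: int) -> pd.DataFrame:
        return self.table.loc[self.table["linkage_group"] == group]


@dataclass
class GenotypeMatrix:
    """Backcross genotypes: samples x markers, entries in {0, 1, NaN}.

    A backcross segregates two genotype classes per marker (homozygote vs
    heterozygote), coded 0/1; NaN marks a missing call.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        ok = np.isnan(arr) | (arr == 0.0) | (arr == 1.0)
        if not ok.all():
            bad = np.unique(arr[~ok & ~np.isnan(arr)])
            raise ValueError(f"genotype entries must be 0/1/NA; found {bad[:5]}")
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.values.columns)

    def check_against_map(self, gmap: GeneticMap) -> None:
        if list(self.values.columns) != gmap.marker_ids:
            raise ValueError("genotype columns do not match the genetic map markers")


@dataclass
class StudyBundle:
    """Everything one analysis consumes: omics layers, traits, genetics.

    Invariants: feature IDs are globally unique across layers and every
    layer shares at least ``min_shared_samples`` samples with the trait
    table.
    """

    layers: list[OmicsDataset]
    traits: pd.DataFrame  # samples x traits
    genotypes: Optional[GenotypeMatrix] = None
    gmap: Optional[GeneticMap] = None
    annotation: Optional[pd.DataFrame] = None  # feature_id, linkage_group, position_cM
    min_shared_samples: int = 10

    def __post_init__(self) -> None:
        self.traits.index = self.traits.index.astype(str)
        seen: dict[str, str] = {}
        for layer in self.layers:
            for fid in layer.feature_ids:
                if fid in seen:
                    raise ValueError(
                        f"duplicate feature ID {fid!r} in layers {seen[fid]!r} and {layer.layer!r}"
                    )
                seen[fid] = layer.layer
        trait_samples = set(self.traits.index)
        for layer in self.layers:
            shared = trait_samples & set(layer.samples)
            if len(shared) < self.min_shared_samples:
                raise AlignmentError(
                    f"layer {layer.layer!r} shares only {len(shared)} samples with the traits "
                    f"(minimum {self.min_shared_samples})"
                )
        if self.genotypes is not None and self.gmap is not None:
            self.genotypes.check_against_map(self.gmap)

    @property
    def has_genetics(self) -> bool:
        return self.genotypes is not None and self.gmap is not None

    def layer_by_name(self, name: str) -> OmicsDataset:
        for layer in self.layers:
            if layer.layer == name:
                return layer
        raise KeyError(f"no layer named {name!r}")

    def annotation_map(self) -> Mapping[str, object]:
        """feature_id -> linkage group (int) or ``unknown``."""
        if self.annotation is None:
            return {}
        out = {}
        for _, row in self.annotation.iterrows():
            grp = row["linkage_group"]
            if isinstance(grp, str) and grp.lower() == UNKNOWN_GROUP:
                out[str(row["feature_id"])] = UNKNOWN_GROUP
            else:
                out[str(row["feature_id"])] = int(grp)
        return out
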