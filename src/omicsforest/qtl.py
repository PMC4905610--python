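"""Marker-regression QTL mapping, cis/trans classification, and
per-chromosome representative selection.

Each trait or omics feature is scanned marker by marker with the
single-marker linear model ``value ~ genotype class``. With two backcross
genotype classes this is exactly a two-group comparison, so the LOD score
is ``(n/2) * log10(RSS0 / RSS1)`` and the p-value is that of the
equal-variance two-sample t-test on the genotype split. Genome-wide
significance is calibrated by permuting the phenotype vector and taking an
upper quantile of the maximum LOD over markers. A feature with a QTL on the
same linkage group as its annotated physical position is cis-acting, on a
different group trans-acting, and unknown when unannotated.

For network construction, redundancy among co-localized significant
features is removed by keeping, per omics layer and per linkage group that
carries a trait QTL, the single feature with the highest RF importance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GeneticMap, GenotypeMatrix, UNKNOWN_GROUP
from .rf import SignificantSet

logger = logging.getLogger(__name__)

__all__ = [
    "LOD_CEILING",
    "QTLScan",
    "QTLCall",
    "RepresentativeSet",
    "marker_scan",
    "scan_features",
    "genomewide_threshold",
    "call_qtls",
    "classify_cis_trans",
    "select_representatives",
]

#: LOD assigned to a degenerate perfect fit (residual sum of squares 0).
LOD_CEILING = 50.0

_MIN_CLASS_SIZE = 2


@dataclass
class QTLScan:
    """Per-marker statistics for one feature or trait."""

    feature_id: str
    table: pd.DataFrame  # marker_id, linkage_group, position_cM, lod, p, n_used, skipped

    @property
    def max_lod(self) -> float:
        ok = self.table.loc[~self.table["skipped"], "lod"]
        return float(ok.max()) if len(ok) else 0.0


@dataclass
class QTLCall:
    feature_id: str
    linkage_group: int
    peak_marker: str
    peak_lod: float
    genomewide_threshold: float
    support_interval: tuple[float, float]
    regulation: str = UNKNOWN_GROUP  # cis | trans | unknown

    def __post_init__(self) -> None:
        if self.peak_lod < self.genomewide_threshold:
            raise ValueError("peak LOD below the genome-wide threshold")


@dataclass
class RepresentativeSet:
    trait: str
    entries: pd.DataFrame  # layer, linkage_group, feature_id, importance, peak_lod

    @property
    def feature_ids(self) -> list[str]:
        return list(self.entries["feature_id"])

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# the scan

def _scan_arrays(
    Y: np.ndarray, G: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized single-marker scan of phenotype columns Y (n x q) against
    genotype columns G (n x m).

    Returns (lod, p, n_used, skipped) each of shape (m, q) except
    n_used/skipped of shape (m, q). Missing genotypes are dropped
    marker-wise; a marker is skipped for a phenotype when either genotype
    class has fewer than two informative individuals.
    """
    n, m = G.shape
    q = Y.shape[1]
    valid = ~np.isnan(G)  # n x m
    g1 = np.where(valid, G, 0.0)  # 1-class indicator (0 where invalid)
    g0 = np.where(valid, 1.0 - G, 0.0)

    yok = ~np.isnan(Y)
    Y0 = np.where(yok, Y, 0.0)

    # per (marker, phenotype) counts restricted to jointly observed entries
    n1 = yok.T.astype(float) @ g1  # q x m -> transpose later
    n0 = yok.T.astype(float) @ g0
    s1 = Y0.T @ g1
    s0 = Y0.T @ g0
    ss = (Y0**2).T @ (g1 + g0)

    n_used = n0 + n1
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_all = (s0 + s1) / n_used
        rss0 = ss - n_used * mean_all**2
        rss1 = ss - np.where(n0 > 0, s0**2 / np.where(n0 > 0, n0, 1), 0.0) - np.where(
            n1 > 0, s1**2 / np.where(n1 > 0, n1, 1), 0.0
        )
    rss0 = np.maximum(rss0, 0.0)
    rss1 = np.maximum(rss1, 0.0)

    skipped = (n0 < _MIN_CLASS_SIZE) | (n1 < _MIN_CLASS_SIZE)

    lod = np.zeros_like(rss0)
    p = np.ones_like(rss0)
    df2 = n_used - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        active = (~skipped) & (rss0 > 0)
        perfect = active & (rss1 <= 1e-300 * np.maximum(rss0, 1.0))
        regular = active & ~perfect
        lod_reg = (n_used / 2.0) * np.log10(np.where(regular, rss0 / np.where(regular, rss1, 1.0), 1.0))
        lod[regular] = np.minimum(lod_reg[regular], LOD_CEILING)
        lod[perfect] = LOD_CEILING
        F = np.zeros_like(rss0)
        F[regular] = (rss0[regular] - rss1[regular]) / (rss1[regular] / df2[regular])
        p[regular] = stats.f.sf(F[regular], 1, df2[regular])
        p[perfect] = np.finfo(float).tiny
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    lod[skipped] = np.nan
    p[skipped] = np.nan
    # (q x m) -> (m x q)
    return lod.T, p.T, n_used.T, np.broadcast_to(skipped, lod.shape).T


def marker_scan(
    values: pd.Series, genotypes: GenotypeMatrix, gmap: GeneticMap
) -> QTLScan:
    """Scan one phenotype (trait or omics feature) against every marker.

    A constant phenotype yields an all-zero scan with a warning. Markers
    where a genotype class has fewer than two individuals are skipped and
    flagged.
    """
    geno = genotypes.values
    if set(values.index) != set(geno.index):
        shared = values.index.intersection(geno.index)
        if len(shared) < 4:
            raise ValueError("phenotype and genotype samples do not overlap")
        values = values.loc[shared]
        geno = geno.loc[shared]
    else:
        geno = geno.loc[values.index]
    genotypes.check_against_map(gmap)

    y = values.to_numpy(dtype=float)[:, None]
    if np.nanstd(y) == 0:
        warnings.warn(
            f"phenotype {values.name!r} is constant; scan is all zero", UserWarning, stacklevel=2
        )
        tab = gmap.table.copy()
        tab["lod"] = 0.0
        tab["p"] = 1.0
        tab["n_used"] = float(len(values))
        tab["skipped"] = False
        return QTLScan(str(values.name), tab)

    lod, p, n_used, skipped = _scan_arrays(y, geno.to_numpy(dtype=float))
    tab = gmap.table.copy()
    tab["lod"] = lod[:, 0]
    tab["p"] = p[:, 0]
    tab["n_used"] = n_used[:, 0]
    tab["skipped"] = skipped[:, 0]
    return QTLScan(str(values.name), tab)


def scan_features(
    values: pd.DataFrame, genotypes: GenotypeMatrix, gmap: GeneticMap
) -> dict[str, QTLScan]:
    """Vectorized scans for many phenotypes (columns of ``values``)."""
    geno = genotypes.values.loc[values.index]
    genotypes.check_against_map(gmap)
    lod, p, n_used, skipped = _scan_arrays(
        values.to_numpy(dtype=float), geno.to_numpy(dtype=float)
    )
    scans = {}
    for j, name in enumerate(values.columns):
        tab = gmap.table.copy()
        tab["lod"] = lod[:, j]
        tab["p"] = p[:, j]
        tab["n_used"] = n_used[:, j]
        tab["skipped"] = skipped[:, j]
        scans[str(name)] = QTLScan(str(name), tab)
    return scans


def genomewide_threshold(
    values: pd.Series,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """(1 - alpha) quantile of the max-over-markers LOD under permutation
    of the phenotype vector."""
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse quantile resolution", UserWarning,
                      stacklevel=2)
    geno = genotypes.values.loc[values.index].to_numpy(dtype=float)
    y = values.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    lod, _, _, _ = _scan_arrays(perms, geno)  # m x n_perm
    max_lod = np.nanmax(lod, axis=0)
    return float(np.quantile(max_lod, 1 - alpha))


def _support_interval(sub: pd.DataFrame, peak_idx: int, drop: float = 1.5) -> tuple[float, float]:
    """Contiguous run of markers around the peak whose LOD stays within
    ``drop`` of the peak LOD (the conventional 1.5-LOD support interval)."""
    lods = sub["lod"].to_numpy()
    pos = sub["position_cM"].to_numpy()
    peak_lod = lods[peak_idx]
    lo = peak_idx
    while lo > 0 and not np.isnan(lods[lo - 1]) and lods[lo - 1] >= peak_lod - drop:
        lo -= 1
    hi = peak_idx
    while hi < len(lods) - 1 and not np.isnan(lods[hi + 1]) and lods[hi + 1] >= peak_lod - drop:
        hi += 1
    return float(pos[lo]), float(pos[hi])


def call_qtls(scan: QTLScan, threshold: float, gmap: GeneticMap) -> list[QTLCall]:
    """One call per linkage group whose maximum LOD exceeds the threshold.

    The peak is the argmax marker (ties broken by smallest cM position);
    the support interval is the 1.5-LOD drop around the peak.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    calls: list[QTLCall] = []
    for group, sub in scan.table.groupby("linkage_group", sort=True):
        sub = sub.reset_index(drop=True)
        lods = sub["lod"].to_numpy()
        if np.all(np.isnan(lods)):
            continue
        peak_idx = int(np.nanargmax(lods))  # first max = smallest cM (rows map-ordered)
        peak_lod = float(lods[peak_idx])
        if peak_lod <= threshold:
            continue
        calls.append(
            QTLCall(
                feature_id=scan.feature_id,
                linkage_group=int(group),
                peak_marker=str(sub["marker_id"].iloc[peak_idx]),
                peak_lod=peak_lod,
                genomewide_threshold=float(threshold),
                support_interval=_support_interval(sub, peak_idx),
            )
        )
    return calls


def classify_cis_trans(call: QTLCall, annotation: Mapping[str, object]) -> str:
    """cis if the feature's annotated physical linkage group equals the QTL
    group, trans if annotated elsewhere, unknown if unannotated."""
    grp = annotation.get(call.feature_id, UNKNOWN_GROUP)
    if grp is None or (isinstance(grp, str) and grp.lower() == UNKNOWN_GROUP):
        return "unknown"
    if isinstance(grp, float) and np.isnan(grp):
        return "unknown"
    return "cis" if int(grp) == call.linkage_group else "trans"


def select_representatives(
    sets: Sequence[SignificantSet],
    feature_calls: Mapping[str, Sequence[QTLCall]],
    trait_calls: Sequence[QTLCall],
    trait: str = "trait",
) -> RepresentativeSet:
    """Per layer and per linkage group carrying a trait QTL, keep the single
    significant feature with a QTL there that has the highest RF importance
    (ties: higher peak LOD, then lexicographic feature ID)."""
    trait_groups = sorted({c.linkage_group for c in trait_calls})
    if not trait_groups:
        warnings.warn("no trait QTL anywhere; representative set is empty", UserWarning,
                      stacklevel=2)
    rows = []
    for s in sets:
        importance = dict(zip(s.features["feature_id"], s.features["importance"]))
        for group in trait_groups:
            candidates = []
            for fid in s.feature_ids:
                for call in feature_calls.get(fid, []):
                    if call.linkage_group == group:
                        candidates.append((importance[fid], call.peak_lod, fid))
            if not candidates:
                continue
            best = min(candidates, key=lambda t: (-t[0], -t[1], t[2]))
            rows.append((s.layer, group, best[2], best[0], best[1]))
    entries = pd.DataFrame(
        rows, columns=["layer", "linkage_group", "feature_id", "importance", "peak_lod"]
    )
    return RepresentativeSet(trait, entries)
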