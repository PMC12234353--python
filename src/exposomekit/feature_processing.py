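"""Untargeted LC-HRMS feature-table treatment.

Takes two per-ionization-mode aligned feature tables (peak areas over
study samples, procedural blanks and pooled QC injections, with per-feature
m/z, retention time and a deconvoluted MS2 spectrum) and produces one
cleaned feature matrix.  Stages, in the order they run:

1. blank-ratio filter   — keep features whose sample maximum exceeds the
                          procedural-blank average by a factor (default 5x)
2. ESI+/ESI- merge      — collapse cross-mode duplicates of the same
                          neutral molecule ([M+H]+ vs [M-H]-)
3. IS-PCA normalization — remove instrument drift estimated from the
                          principal components of the isotope-labeled
                          internal-standard intensities
4. blank subtract/floor — per-cell 5x blank gating, blank subtraction,
                          and a hard area floor (default 90,000)
5. correlation dedup    — drop in-source fragments / adducts (r > 0.95,
                          p < 0.001, RT within 0.1 min)
6. DF filter            — keep features detected in >= 70% of samples

Every removal is recorded in a provenance log (stage, feature, reason).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: mass of a proton in Da, used for [M+H]+ / [M-H]- neutral-mass arithmetic
PROTON_MASS = 1.007276

POSITIVE = "ESI+"
NEGATIVE = "ESI-"

META_COLUMNS = ["mz", "rt", "mode", "ms2"]


@dataclass
class RawFeatureTable:
    """An aligned feature table for one (or a merged pair of) ESI mode(s).

    ``meta`` holds per-feature m/z (measured ion), RT in minutes, mode and
    the MS2 spectrum serialized as space-separated ``mz:intensity`` pairs.
    ``areas`` holds peak areas with one column per study sample, procedural
    blank and pooled QC injection; the three roles are tracked explicitly.
    """

    meta: pd.DataFrame
    areas: pd.DataFrame
    sample_cols: list[str]
    blank_cols: list[str]
    qc_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.areas.index):
            raise ValueError("meta and areas must share the feature index")
        declared = set(self.sample_cols) | set(self.blank_cols) | set(self.qc_cols)
        if declared != set(self.areas.columns):
            raise ValueError("sample/blank/QC roles must cover the area columns exactly")
        if (self.areas.to_numpy() < 0).any():
            raise ValueError("peak areas must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.meta)

    def copy(self) -> "RawFeatureTable":
        return RawFeatureTable(
            self.meta.copy(), self.areas.copy(),
            list(self.sample_cols), list(self.blank_cols), list(self.qc_cols),
        )

    def subset(self, feature_ids: Sequence[str]) -> "RawFeatureTable":
        idx = [f for f in self.meta.index if f in set(feature_ids)]
        return RawFeatureTable(
            self.meta.loc[idx].copy(), self.areas.loc[idx].copy(),
            list(self.sample_cols), list(self.blank_cols), list(self.qc_cols),
        )

    def neutral_mass(self) -> pd.Series:
        """Neutral mass M from the measured ion m/z and the ESI mode."""
        sign = self.meta["mode"].map({POSITIVE: -1.0, NEGATIVE: 1.0})
        if sign.isna().any():
            bad = self.meta.index[sign.isna()][0]
            raise ValueError(f"unknown ESI mode for feature {bad!r}")
        return self.meta["mz"] + sign * PROTON_MASS

    def average_sample_area(self) -> pd.Series:
        return self.areas[self.sample_cols].mean(axis=1)

    def write(self, path: str | Path) -> None:
        """Write in an MS-DIAL-alignment-like delimited layout."""
        out = self.meta.copy()
        out.insert(0, "feature_id", out.index)
        renamed = {c: _role_prefix(self, c) + c for c in self.areas.columns}
        out = pd.concat([out.reset_index(drop=True),
                         self.areas.rename(columns=renamed).reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)


def _role_prefix(table: RawFeatureTable, col: str) -> str:
    if col in table.blank_cols:
        return "blank::"
    if col in table.qc_cols:
        return "qc::"
    return "sample::"


def read_feature_table(path: str | Path) -> RawFeatureTable:
    """Read a table written by :meth:`RawFeatureTable.write`."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    df = df.set_index("feature_id")
    meta = df[META_COLUMNS].copy()
    meta["ms2"] = meta["ms2"].fillna("")
    sample_cols, blank_cols, qc_cols, rename = [], [], [], {}
    for c in df.columns:
        if c in META_COLUMNS:
            continue
        role, _, name = c.partition("::")
        rename[c] = name
        {"sample": sample_cols, "blank": blank_cols, "qc": qc_cols}[role].append(name)
    areas = df.drop(columns=META_COLUMNS).rename(columns=rename).astype(float)
    return RawFeatureTable(meta, areas, sample_cols, blank_cols, qc_cols)


@dataclass
class CleanedFeatureMatrix:
    """Final feature x sample areas with detection frequencies and provenance."""

    areas: pd.DataFrame  # features x study samples only
    df: pd.Series  # detection frequency per retained feature
    meta: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return len(self.areas)


def _log_removals(
    provenance: list[dict] | None, stage: str, removed: Sequence[str], **params
) -> None:
    if provenance is None:
        return
    for fid in removed:
        provenance.append({"stage": stage, "feature_id": fid, **params})


# ---------------------------------------------------------------------------
# stage 1: blank-ratio filter


def max_blank_ratio_filter(
    table: RawFeatureTable,
    factor: float = 5.0,
    provenance: list[dict] | None = None,
) -> RawFeatureTable:
    """Keep features whose sample maximum exceeds ``factor`` x blank average.

    A blank average of zero retains any feature with a detected sample
    area.  At least one procedural-blank column is required.
    """
    if not table.blank_cols:
        raise ValueError("blank-ratio filter requires at least one blank column")
    smax = table.areas[table.sample_cols].max(axis=1)
    bmean = table.areas[table.blank_cols].mean(axis=1)
    keep = (smax > factor * bmean) & (smax > 0)
    _log_removals(provenance, "blank_ratio", list(table.meta.index[~keep]), factor=factor)
    return table.subset(list(table.meta.index[keep]))


# ---------------------------------------------------------------------------
# stage 2: ESI mode merging


def merge_esi_modes(
    pos: RawFeatureTable,
    neg: RawFeatureTable,
    rt_tol: float = 0.2,
    mz_tol: float = 0.002,
    provenance: list[dict] | None = None,
) -> RawFeatureTable:
    """Collapse cross-mode duplicates of the same neutral molecule.

    Neutral masses are computed as m/z - 1.007276 (ESI+) and m/z + 1.007276
    (ESI-).  For every cross-mode pair agreeing within ``mz_tol`` Da on
    neutral mass and ``rt_tol`` min on RT, the member with the lower
    average sample peak area is discarded.
    """
    if pos.sample_cols != neg.sample_cols:
        raise ValueError("positive and negative tables must share sample columns")
    pm = pos.neutral_mass().to_numpy()
    nm = neg.neutral_mass().to_numpy()
    prt = pos.meta["rt"].to_numpy()
    nrt = neg.meta["rt"].to_numpy()
    pavg = pos.average_sample_area()
    navg = neg.average_sample_area()
    drop_pos: set[str] = set()
    drop_neg: set[str] = set()
    for i, fid in enumerate(pos.meta.index):
        if fid in drop_pos:
            continue
        hit = (np.abs(nm - pm[i]) <= mz_tol) & (np.abs(nrt - prt[i]) <= rt_tol)
        for j in np.flatnonzero(hit):
            nfid = neg.meta.index[j]
            if nfid in drop_neg:
                continue
            if pavg.iloc[i] >= navg.iloc[j]:
                drop_neg.add(nfid)
            else:
                drop_pos.add(fid)
                break
    _log_removals(provenance, "esi_merge", sorted(drop_pos) + sorted(drop_neg),
                  rt_tol=rt_tol, mz_tol=mz_tol)
    pos_kept = pos.subset([f for f in pos.meta.index if f not in drop_pos])
    neg_kept = neg.subset([f for f in neg.meta.index if f not in drop_neg])
    meta_parts = [t.meta for t in (pos_kept, neg_kept) if len(t.meta)]
    area_parts = [t.areas for t in (pos_kept, neg_kept) if len(t.areas)]
    meta = pd.concat(meta_parts) if meta_parts else pos_kept.meta
    areas = pd.concat(area_parts) if area_parts else pos_kept.areas
    # blanks/QC are mode-specific columns; keep the union
    blank_cols = list(dict.fromkeys(pos.blank_cols + neg.blank_cols))
    qc_cols = list(dict.fromkeys(pos.qc_cols + neg.qc_cols))
    areas = areas.reindex(columns=pos.sample_cols + blank_cols + qc_cols).fillna(0.0)
    return RawFeatureTable(meta, areas, list(pos.sample_cols), blank_cols, qc_cols)


# ---------------------------------------------------------------------------
# stage 3: internal-standard PCA normalization


def is_pca_correction(
    is_matrix: pd.DataFrame, n_components: int = 2
) -> pd.Series:
    """Per-sample multiplicative drift correction from the IS intensities.

    The log IS matrix (internal standards x samples) is transposed,
    column-centered, and projected onto its first ``n_components``
    principal components; the per-sample drift is the mean over internal
    standards of the low-rank reconstruction, recentered to unit geometric
    mean.  Returned on the log scale (subtract from log areas, i.e. divide
    areas by ``exp(correction)``).
    """
    if len(is_matrix) < 2:
        raise ValueError("IS-PCA normalization requires >= 2 internal standards")
    logm = np.log(is_matrix.where(is_matrix > 0))
    dead = logm.isna().all(axis=0)
    if dead.any():
        raise ValueError(f"sample {dead.index[dead][0]!r} has no internal-standard signal")
    # occasional missing IS: impute with that standard's mean log intensity
    logm = logm.apply(lambda row: row.fillna(row.mean()), axis=1)
    X = logm.T.to_numpy()  # samples x IS
    X = X - X.mean(axis=0, keepdims=True)
    k = min(n_components, min(X.shape))
    if n_components <= 0 or not np.any(X):
        return pd.Series(0.0, index=is_matrix.columns)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    recon = (U[:, :k] * s[:k]) @ Vt[:k]
    drift = recon.mean(axis=1)
    drift = drift - drift.mean()
    return pd.Series(drift, index=is_matrix.columns)


def normalize_by_is_pca(
    table: RawFeatureTable,
    is_matrix: pd.DataFrame,
    n_components: int = 2,
    method: str = "pca",
) -> tuple[RawFeatureTable, pd.DataFrame]:
    """Remove instrument drift from peak areas using the IS signals.

    ``method='pca'`` uses the low-rank PCA drift estimate;
    ``method='median'`` falls back to simple per-sample scaling by the
    median internal-standard ratio.  Only the columns present in
    ``is_matrix`` (the study samples) are corrected; zero areas remain
    zero.  Returns the corrected table and the correspondingly corrected
    IS matrix.
    """
    missing = [c for c in is_matrix.columns if c not in table.areas.columns]
    if missing:
        raise ValueError(f"IS matrix has unknown sample columns: {missing}")
    if method == "pca":
        drift = is_pca_correction(is_matrix, n_components)
    elif method == "median":
        logm = np.log(is_matrix.where(is_matrix > 0))
        drift = logm.median(axis=0)
        drift = drift - drift.mean()
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    factors = np.exp(-drift)
    out = table.copy()
    out.areas.loc[:, drift.index] = out.areas.loc[:, drift.index] * factors
    return out, is_matrix * factors


# ---------------------------------------------------------------------------
# stage 4: blank subtraction and floor


def blank_subtract_floor(
    table: RawFeatureTable,
    factor: float = 5.0,
    pseudo: float = 0.1,
    floor: float = 90000.0,
    provenance: list[dict] | None = None,
) -> RawFeatureTable:
    """Per-cell blank gating, blank subtraction, and hard area floor.

    For each feature the procedural-blank average (plus a 0.1 pseudo-count
    to avoid zero denominators) gates each sample cell at ``factor``;
    passing cells have the blank average subtracted; any resulting area
    below ``floor`` is set to zero.  Blank columns are zeroed afterwards
    (their contribution is consumed), which makes the stage idempotent.
    """
    out = table.copy()
    bmean = out.areas[out.blank_cols].mean(axis=1) if out.blank_cols else pd.Series(
        0.0, index=out.meta.index
    )
    cols = out.sample_cols + out.qc_cols
    vals = out.areas[cols].to_numpy(dtype=float)
    b = bmean.to_numpy()[:, None]
    ratio = vals / (b + pseudo)
    vals = np.where(ratio < factor, 0.0, vals - b)
    vals = np.where(vals < floor, 0.0, vals)
    out.areas.loc[:, cols] = vals
    if out.blank_cols:
        out.areas.loc[:, out.blank_cols] = 0.0
    if provenance is not None:
        provenance.append(
            {"stage": "blank_subtract_floor", "feature_id": None,
             "factor": factor, "pseudo": pseudo, "floor": floor}
        )
    return out


# ---------------------------------------------------------------------------
# stage 5: correlated-feature deduplication


def _pair_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Pearson r and p over co-detected (both nonzero) samples; None if < 3."""
    mask = (x > 0) & (y > 0)
    if mask.sum() < 3:
        return None
    xs, ys = x[mask], y[mask]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return None
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def dedup_correlated(
    table: RawFeatureTable,
    r_threshold: float = 0.95,
    p_threshold: float = 0.001,
    rt_tol: float = 0.1,
    provenance: list[dict] | None = None,
) -> RawFeatureTable:
    """Drop redundant features (in-source fragments, adducts).

    Features are processed in descending average-sample-area order (ties
    broken by feature id); for each survivor, any remaining feature within
    ``rt_tol`` min whose Pearson correlation over co-detected samples
    exceeds ``r_threshold`` at ``p < p_threshold`` is discarded.  Pairs
    with fewer than three co-detected samples are skipped.
    """
    avg = table.average_sample_area()
    order = sorted(table.meta.index, key=lambda f: (-avg.loc[f], f))
    rt = table.meta["rt"]
    vals = {f: table.areas.loc[f, table.sample_cols].to_numpy(dtype=float) for f in order}
    removed: set[str] = set()
    for i, fi in enumerate(order):
        if fi in removed:
            continue
        for fj in order[i + 1:]:
            if fj in removed:
                continue
            if abs(rt.loc[fi] - rt.loc[fj]) > rt_tol:
                continue
            rp = _pair_correlation(vals[fi], vals[fj])
            if rp is None:
                logger.debug("dedup pair (%s, %s) skipped: < 3 co-detected samples", fi, fj)
                continue
            r, p = rp
            if r > r_threshold and p < p_threshold:
                removed.add(fj)
                _log_removals(provenance, "dedup", [fj], kept=fi, r=r, p=p)
    return table.subset([f for f in table.meta.index if f not in removed])


# ---------------------------------------------------------------------------
# stage 6: detection-frequency filter


def detection_frequency_filter(
    table: RawFeatureTable,
    df_threshold: float = 0.70,
    provenance: list[dict] | None = None,
) -> CleanedFeatureMatrix:
    """Keep features detected (area > 0) in at least ``df_threshold`` of samples."""
    detected = table.areas[table.sample_cols] > 0
    df = detected.mean(axis=1)
    keep = df >= df_threshold
    prov = provenance if provenance is not None else []
    _log_removals(prov, "detection_frequency", list(table.meta.index[~keep]),
                  df_threshold=df_threshold)
    return CleanedFeatureMatrix(
        areas=table.areas.loc[keep, table.sample_cols].copy(),
        df=df[keep],
        meta=table.meta.loc[keep].copy(),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# orchestration


def clean_feature_tables(
    pos: RawFeatureTable,
    neg: RawFeatureTable,
    is_matrix: pd.DataFrame,
    blank_factor: float = 5.0,
    mz_tol: float = 0.002,
    rt_tol_merge: float = 0.2,
    is_components: int = 2,
    pseudo: float = 0.1,
    floor: float = 90000.0,
    r_threshold: float = 0.95,
    p_threshold: float = 0.001,
    rt_tol_dedup: float = 0.1,
    df_threshold: float = 0.70,
    normalization: str = "pca",
) -> tuple[CleanedFeatureMatrix, dict[str, int]]:
    """Run the full cleaning cascade; returns the matrix and per-stage counts."""
    provenance: list[dict] = []
    counts = {"input": pos.n_features + neg.n_features}
    pos_f = max_blank_ratio_filter(pos, blank_factor, provenance)
    neg_f = max_blank_ratio_filter(neg, blank_factor, provenance)
    counts["blank_ratio"] = pos_f.n_features + neg_f.n_features
    merged = merge_esi_modes(pos_f, neg_f, rt_tol_merge, mz_tol, provenance)
    counts["esi_merge"] = merged.n_features
    normed, _ = normalize_by_is_pca(merged, is_matrix, is_components, normalization)
    counts["normalized"] = normed.n_features
    treated = blank_subtract_floor(normed, blank_factor, pseudo, floor, provenance)
    counts["blank_subtract_floor"] = treated.n_features
    deduped = dedup_correlated(treated, r_threshold, p_threshold, rt_tol_dedup, provenance)
    counts["dedup"] = deduped.n_features
    cleaned = detection_frequency_filter(deduped, df_threshold, provenance)
    counts["detection_frequency"] = cleaned.n_features
    logger.info("feature cleaning funnel: %s", counts)
    return cleaned, counts
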