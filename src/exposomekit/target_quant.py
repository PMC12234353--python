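"""Targeted analyte quantification with left-censoring.

Concentrations are read off internal-standard response-ratio calibration
curves (default nine points spanning 0.01-100 ng/mL).  Values above the
calibration range are linearly extrapolated and flagged; values below the
method limit of quantification (MLOQ) are censored and substituted by
MLOQ/2 (detected but not quantifiable) or MLOQ/4 (non-detect).  Linear and
branched isomers of the same compound (chromatographically resolved PFAS
isomers, typically) are summed into a single total concentration before
association testing.  Analytes are finally screened on detection
frequency, with a force-include list for analytes of a-priori interest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# cell status vocabulary
QUANTIFIED = "quantified"
EXTRAPOLATED = "extrapolated"
BELOW_MLOQ = "below_mloq"
NONDETECT = "nondetect"
SUB_HALF = "substituted_half_mloq"
SUB_QUARTER = "substituted_quarter_mloq"

STATUSES = (QUANTIFIED, EXTRAPOLATED, BELOW_MLOQ, NONDETECT, SUB_HALF, SUB_QUARTER)
#: statuses that count toward the targeted detection frequency (default reading)
DETECTED_STATUSES = (QUANTIFIED, EXTRAPOLATED)
#: statuses produced by censoring substitution
SUBSTITUTED_STATUSES = (SUB_HALF, SUB_QUARTER)

ISOMER_SUFFIXES = ("_linear", "_branched")


@dataclass(frozen=True)
class Calibration:
    """A fitted response-ratio calibration line for one analyte."""

    analyte: str
    internal_standard: str
    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    range: tuple[float, float]

    def concentration(self, ratio: float) -> float:
        """Invert the line: concentration from a response ratio."""
        return (ratio - self.intercept) / self.slope


@dataclass(frozen=True)
class QuantifiedValue:
    """A single concentration cell with its censoring status."""

    value: float
    status: str
    analyte: str | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass
class ConcentrationMatrix:
    """Analyte x sample concentrations with per-cell censoring status.

    ``values`` and ``status`` share the same index (analytes) and columns
    (samples).  ``mloq`` and ``analyte_class`` are indexed by analyte.
    """

    values: pd.DataFrame
    status: pd.DataFrame
    mloq: pd.Series
    analyte_class: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.status.index) or not self.values.columns.equals(
            self.status.columns
        ):
            raise ValueError("values and status must share index and columns")
        missing = self.values.index.difference(self.mloq.index)
        if len(missing):
            raise ValueError(f"no MLOQ for analytes: {list(missing)}")
        if (self.mloq.loc[self.values.index] <= 0).any():
            raise ValueError("every MLOQ must be > 0")
        if self.analyte_class is None:
            self.analyte_class = pd.Series("unknown", index=self.values.index)

    @property
    def analytes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "ConcentrationMatrix":
        return ConcentrationMatrix(
            self.values.copy(), self.status.copy(), self.mloq.copy(), self.analyte_class.copy()
        )

    def detection_frequency(self, detected: Sequence[str] = DETECTED_STATUSES) -> pd.Series:
        """Per-analyte fraction of samples whose status is in ``detected``."""
        return self.status.isin(set(detected)).mean(axis=1)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table (analyte, sample, value, status)."""
        v = self.values.stack()
        s = self.status.stack()
        out = pd.DataFrame({"value": v, "status": s}).reset_index()
        out.columns = ["analyte", "sample", "value", "status"]
        return out


# ---------------------------------------------------------------------------
# calibration


def fit_calibration(
    points: Iterable[tuple[float, float]],
    analyte: str = "",
    internal_standard: str = "",
) -> Calibration:
    """Ordinary least-squares line through (concentration, response ratio) points.

    Raises ``ValueError`` when fewer than two distinct concentrations are
    supplied (the fit is degenerate).
    """
    pts = tuple((float(c), float(r)) for c, r in points)
    conc = np.array([p[0] for p in pts])
    ratio = np.array([p[1] for p in pts])
    if len(np.unique(conc)) < 2:
        raise ValueError("calibration requires >= 2 distinct concentrations")
    design = np.column_stack([conc, np.ones_like(conc)])
    (slope, intercept), *_ = np.linalg.lstsq(design, ratio, rcond=None)
    return Calibration(
        analyte=analyte,
        internal_standard=internal_standard,
        points=pts,
        slope=float(slope),
        intercept=float(intercept),
        range=(float(conc.min()), float(conc.max())),
    )


def average_calibrations(cals: Sequence[Calibration]) -> Calibration:
    """Average repeated curve injections into one calibration.

    Slopes and intercepts are averaged; the range is the union of the
    individual ranges.  Used to combine the replicate injections run at the
    beginning, middle and end of each batch sequence.
    """
    if not cals:
        raise ValueError("no calibrations to average")
    analytes = {c.analyte for c in cals}
    if len(analytes) > 1:
        raise ValueError(f"cannot average calibrations across analytes {sorted(analytes)}")
    return Calibration(
        analyte=cals[0].analyte,
        internal_standard=cals[0].internal_standard,
        points=tuple(p for c in cals for p in c.points),
        slope=float(np.mean([c.slope for c in cals])),
        intercept=float(np.mean([c.intercept for c in cals])),
        range=(min(c.range[0] for c in cals), max(c.range[1] for c in cals)),
    )


# ---------------------------------------------------------------------------
# quantification


def quantify(area: float, is_area: float, cal: Calibration, mloq: float) -> QuantifiedValue:
    """Convert one peak area to a concentration with censoring status.

    ``area`` of zero (no integrable peak) yields a non-detect.  A value
    above the upper calibration bound is retained but flagged
    ``extrapolated``; the boundary itself counts as in-range.  A positive
    value below the MLOQ is flagged ``below_mloq``.  ``is_area`` must be
    positive.
    """
    if is_area <= 0:
        raise ValueError("internal standard area must be > 0")
    if mloq <= 0:
        raise ValueError("MLOQ must be > 0")
    if area <= 0:
        return QuantifiedValue(0.0, NONDETECT, cal.analyte or None)
    value = cal.concentration(area / is_area)
    if value <= 0:
        return QuantifiedValue(0.0, NONDETECT, cal.analyte or None)
    if value > cal.range[1]:
        status = EXTRAPOLATED
    elif value < mloq:
        status = BELOW_MLOQ
    else:
        status = QUANTIFIED
    return QuantifiedValue(float(value), status, cal.analyte or None)


def quantify_matrix(
    areas: pd.DataFrame,
    is_areas: pd.DataFrame,
    calibrations: Mapping[str, Calibration] | Mapping[tuple[str, int], Calibration],
    mloqs: Mapping[str, float],
    batches: Mapping[str, int] | None = None,
    analyte_class: Mapping[str, str] | None = None,
) -> ConcentrationMatrix:
    """Quantify an analyte x sample area grid.

    ``calibrations`` is keyed by analyte, or by (analyte, batch) when
    ``batches`` maps sample -> injection batch.  Cells with a non-positive
    internal-standard area are logged and set non-detect rather than
    aborting the whole matrix.
    """
    values = pd.DataFrame(0.0, index=areas.index, columns=areas.columns)
    status = pd.DataFrame(NONDETECT, index=areas.index, columns=areas.columns)
    for analyte in areas.index:
        mloq = float(mloqs[analyte])
        for sample in areas.columns:
            if batches is not None:
                cal = calibrations[(analyte, batches[sample])]  # type: ignore[index]
            else:
                cal = calibrations[analyte]  # type: ignore[index]
            is_area = float(is_areas.loc[analyte, sample])
            if is_area <= 0:
                logger.warning(
                    "non-positive IS area for %s in %s; cell set nondetect", analyte, sample
                )
                continue
            qv = quantify(float(areas.loc[analyte, sample]), is_area, cal, mloq)
            values.loc[analyte, sample] = qv.value
            status.loc[analyte, sample] = qv.status
    mloq_series = pd.Series({a: float(mloqs[a]) for a in areas.index})
    cls = (
        pd.Series({a: analyte_class.get(a, "unknown") for a in areas.index})
        if analyte_class is not None
        else None
    )
    return ConcentrationMatrix(values, status, mloq_series, cls)


# ---------------------------------------------------------------------------
# censoring substitution


def substitute_censored(matrix: ConcentrationMatrix) -> ConcentrationMatrix:
    """Replace censored cells by their MLOQ-based substitution values.

    below_mloq -> MLOQ/2, nondetect -> MLOQ/4; all other cells untouched.
    The operation is idempotent.
    """
    out = matrix.copy()
    mloq = out.mloq.loc[out.analytes]
    below = out.status.eq(BELOW_MLOQ)
    nond = out.status.eq(NONDETECT)
    half = pd.DataFrame(
        np.broadcast_to((mloq / 2).to_numpy()[:, None], out.values.shape),
        index=out.values.index,
        columns=out.values.columns,
    )
    out.values = out.values.mask(below, half).mask(nond, half / 2)
    out.status = out.status.mask(below, SUB_HALF).mask(nond, SUB_QUARTER)
    return out


# ---------------------------------------------------------------------------
# isomer summing


def isomer_family(analyte: str) -> str:
    """Strip a linear/branched suffix to get the isomer family name."""
    for suffix in ISOMER_SUFFIXES:
        if analyte.endswith(suffix):
            return analyte[: -len(suffix)]
    return analyte


# precedence when combining cell statuses in a sum: the "most detected" wins
_STATUS_RANK = {
    EXTRAPOLATED: 5,
    QUANTIFIED: 4,
    BELOW_MLOQ: 3,
    SUB_HALF: 2,
    SUB_QUARTER: 1,
    NONDETECT: 0,
}


def _combine_status(a: str, b: str) -> str:
    return a if _STATUS_RANK[a] >= _STATUS_RANK[b] else b


def sum_isomers(linear: QuantifiedValue, branched: QuantifiedValue) -> QuantifiedValue:
    """Sum linear and branched isomer concentrations into a total.

    Substituted values enter the sum as substituted.  The result is
    ``quantified`` as soon as either input was quantified (or
    ``extrapolated`` if either was); a sum of two substituted cells stays
    flagged as substituted.
    """
    if linear.analyte and branched.analyte:
        if isomer_family(linear.analyte) != isomer_family(branched.analyte):
            raise ValueError(
                f"isomer families differ: {linear.analyte!r} vs {branched.analyte!r}"
            )
    family = isomer_family(linear.analyte) if linear.analyte else None
    return QuantifiedValue(linear.value + branched.value, _combine_status(linear.status, branched.status), family)


def sum_isomers_matrix(
    matrix: ConcentrationMatrix, pairs: Mapping[str, Sequence[str]] | None = None
) -> ConcentrationMatrix:
    """Collapse linear/branched isomer rows into per-family total rows.

    ``pairs`` maps total-row name -> member analytes; by default every
    group of rows sharing an isomer family (``*_linear``/``*_branched``)
    is summed into ``"<family> (total)"``.  Non-isomer rows pass through.
    """
    if pairs is None:
        fams: dict[str, list[str]] = {}
        for a in matrix.analytes:
            if a != isomer_family(a):
                fams.setdefault(isomer_family(a), []).append(a)
        pairs = {f"{fam} (total)": members for fam, members in fams.items() if len(members) >= 2}
    consumed = {m for members in pairs.values() for m in members}
    missing = consumed - set(matrix.analytes)
    if missing:
        raise ValueError(f"isomer members absent from matrix: {sorted(missing)}")

    rows_v, rows_s, mloq, cls = {}, {}, {}, {}
    for a in matrix.analytes:
        if a in consumed:
            continue
        rows_v[a] = matrix.values.loc[a]
        rows_s[a] = matrix.status.loc[a]
        mloq[a] = matrix.mloq.loc[a]
        cls[a] = matrix.analyte_class.loc[a]
    for total, members in pairs.items():
        fam = {isomer_family(m) for m in members}
        if len(fam) > 1:
            raise ValueError(f"group {total!r} mixes isomer families {sorted(fam)}")
        vals = matrix.values.loc[list(members)].sum(axis=0)
        stat = matrix.status.loc[members[0]]
        for m in members[1:]:
            stat = pd.Series(
                [_combine_status(x, y) for x, y in zip(stat, matrix.status.loc[m])],
                index=stat.index,
            )
        rows_v[total] = vals
        rows_s[total] = stat
        # totals inherit the smallest member MLOQ: the most sensitive channel
        mloq[total] = float(matrix.mloq.loc[list(members)].min())
        cls[total] = matrix.analyte_class.loc[members[0]]
    values = pd.DataFrame(rows_v).T
    status = pd.DataFrame(rows_s).T
    values.columns = matrix.samples
    status.columns = matrix.samples
    return ConcentrationMatrix(values, status, pd.Series(mloq), pd.Series(cls))


# ---------------------------------------------------------------------------
# detection-frequency screening


def select_targets(
    matrix: ConcentrationMatrix,
    threshold: float = 0.60,
    force_include: Sequence[str] = (),
    df_mode: str = "quantified",
) -> list[str]:
    """Retain analytes whose detection frequency meets ``threshold``.

    ``df_mode='quantified'`` (default) counts the fraction of samples that
    did not require censoring substitution (quantified or extrapolated).
    ``df_mode='detected'`` counts every status except non-detect, i.e. it
    treats below-MLOQ detections as detected.  Analytes in
    ``force_include`` are kept regardless; a forced analyte missing from
    the matrix is warned about and skipped.  The threshold is inclusive.
    """
    if df_mode == "quantified":
        detected = DETECTED_STATUSES
    elif df_mode == "detected":
        detected = (QUANTIFIED, EXTRAPOLATED, BELOW_MLOQ, SUB_HALF)
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    df = matrix.detection_frequency(detected)
    retained = [a for a in matrix.analytes if df.loc[a] >= threshold]
    for a in force_include:
        if a not in matrix.analytes:
            warnings.warn(f"force-include analyte {a!r} absent from matrix; skipped")
            continue
        if a not in retained:
            retained.append(a)
    return retained


def reference_standardize(
    values: pd.Series | pd.DataFrame, qc_measured: float, qc_reference: float
) -> pd.Series | pd.DataFrame:
    """Scale hormone concentrations by a pooled-QC reference ratio.

    Multiplies by ``qc_reference / qc_measured`` so the pooled QC sample
    reads at its assigned reference value.
    """
    if qc_measured <= 0 or qc_reference <= 0:
        raise ValueError("QC values must be positive")
    return values * (qc_reference / qc_measured)
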