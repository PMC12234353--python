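"""Confidence-levelled spectral-library annotation of cleaned features.

Features are matched against MSP/MGF spectral libraries by binned dot- and
reverse-dot-product scores on a 0-1000 scale.  The best-scoring entry
yields a Level 2 annotation when the total identification score exceeds
700 with a dot or reverse-dot score above 600; the annotation is upgraded
to Level 1 when the entry carries a reference-standard retention time that
matches the feature.  Annotated compounds are classified as environmental,
endogenous or (on conflicting metadata) ambiguous, with a free-text
subclass (PFAS, bile acids, ...).

The total identification score is the mean of the dot and reverse-dot
scores; intensities are square-root weighted before the cosine by default.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LEVEL_NONE = 0

ENVIRONMENTAL = "environmental"
ENDOGENOUS = "endogenous"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class LibraryEntry:
    """One reference spectrum with identity and class metadata."""

    name: str
    precursor_mz: float
    ms2: tuple[tuple[float, float], ...]
    rt: float | None = None  # present only for in-house reference standards
    class_meta: str = AMBIGUOUS
    subclass: str = ""

    def __post_init__(self) -> None:
        if not self.ms2:
            raise ValueError(f"library entry {self.name!r} has an empty MS2 spectrum")
        if any(i < 0 for _, i in self.ms2):
            raise ValueError(f"library entry {self.name!r} has negative intensities")


@dataclass
class AnnotationRecord:
    """Annotation outcome for one feature."""

    feature_id: str
    level: int  # 1, 2, or 0 for unannotated
    matched_name: str = ""
    dot: float = 0.0
    revdot: float = 0.0
    total: float = 0.0
    class_meta: str = ""
    subclass: str = ""


# ---------------------------------------------------------------------------
# spectrum helpers


def parse_ms2(text: str) -> list[tuple[float, float]]:
    """Parse a serialized ``mz:intensity mz:intensity ...`` spectrum."""
    if not text or not str(text).strip():
        return []
    out = []
    for token in str(text).split():
        mz, _, inten = token.partition(":")
        out.append((float(mz), float(inten)))
    return out


def format_ms2(peaks: Iterable[tuple[float, float]]) -> str:
    return " ".join(f"{mz:.4f}:{inten:.1f}" for mz, inten in peaks)


def _bin_spectrum(
    peaks: Sequence[tuple[float, float]], bin_tol: float, sqrt_weight: bool
) -> dict[int, float]:
    binned: dict[int, float] = defaultdict(float)
    for mz, inten in peaks:
        binned[round(mz / bin_tol)] += inten
    if sqrt_weight:
        return {k: np.sqrt(v) for k, v in binned.items()}
    return dict(binned)


# ---------------------------------------------------------------------------
# scoring


def spectral_scores(
    query: Sequence[tuple[float, float]],
    ref: Sequence[tuple[float, float]],
    bin_tol: float = 0.01,
    sqrt_weight: bool = True,
) -> tuple[float, float]:
    """Dot and reverse-dot product scores on the 0-1000 scale.

    Peaks are binned at ``bin_tol`` Da and (by default) square-root
    intensity weighted.  The dot product is the cosine similarity over the
    union of bins; the reverse dot product is the same cosine restricted
    to the bins present in the reference spectrum, so extra query peaks
    (matrix noise, co-eluting fragments) do not penalize it.
    """
    if not query or not ref:
        raise ValueError("spectral scoring requires non-empty spectra")
    q = _bin_spectrum(query, bin_tol, sqrt_weight)
    r = _bin_spectrum(ref, bin_tol, sqrt_weight)

    def cosine(qv: dict[int, float], rv: dict[int, float]) -> float:
        num = sum(qv.get(k, 0.0) * rv[k] for k in rv)
        den = np.sqrt(sum(v * v for v in qv.values())) * np.sqrt(
            sum(v * v for v in rv.values())
        )
        return 0.0 if den == 0 else num / den

    dot = cosine(q, r)
    q_restricted = {k: v for k, v in q.items() if k in r}
    rev = cosine(q_restricted, r) if q_restricted else 0.0
    return 1000.0 * dot, 1000.0 * rev


# ---------------------------------------------------------------------------
# level assignment


def assign_level(
    feature_id: str,
    query_ms2: Sequence[tuple[float, float]],
    query_rt: float,
    candidates: Sequence[LibraryEntry],
    bin_tol: float = 0.01,
    rt_tol: float = 0.2,
    total_threshold: float = 700.0,
    dot_threshold: float = 600.0,
    sqrt_weight: bool = True,
) -> AnnotationRecord:
    """Score a feature against candidate entries and assign a confidence level.

    The entry with the best total score (mean of dot and reverse dot) is
    taken.  Level 2 requires total > ``total_threshold`` and dot or
    reverse dot > ``dot_threshold`` (strict inequalities); Level 1
    additionally requires the entry to carry a reference RT matching the
    feature within ``rt_tol`` minutes.
    """
    if not query_ms2 or not candidates:
        return AnnotationRecord(feature_id, LEVEL_NONE)
    best: tuple[float, float, float, LibraryEntry] | None = None
    for entry in candidates:
        dot, rev = spectral_scores(query_ms2, entry.ms2, bin_tol, sqrt_weight)
        total = (dot + rev) / 2.0
        if best is None or total > best[0]:
            best = (total, dot, rev, entry)
    total, dot, rev, entry = best
    level = LEVEL_NONE
    if total > total_threshold and (dot > dot_threshold or rev > dot_threshold):
        level = 2
        if entry.rt is not None and abs(query_rt - entry.rt) <= rt_tol:
            level = 1
    if level == LEVEL_NONE:
        return AnnotationRecord(feature_id, LEVEL_NONE, entry.name, dot, rev, total)
    return AnnotationRecord(
        feature_id, level, entry.name, dot, rev, total, entry.class_meta, entry.subclass
    )


def classify_feature(
    record: AnnotationRecord,
    sources: Sequence[tuple[str, str]],
) -> tuple[str, str]:
    """Resolve class/subclass from one or more metadata sources.

    ``sources`` lists (class, subclass) opinions, e.g. from the library
    entry plus external compound databases.  Disagreeing class opinions
    yield ``ambiguous``; the subclass is the most common non-empty one.
    """
    if record.level not in (1, 2):
        raise ValueError(f"feature {record.feature_id!r} is unannotated; cannot classify")
    if not sources:
        raise ValueError("at least one metadata source is required")
    classes = {c for c, _ in sources if c}
    class_meta = classes.pop() if len(classes) == 1 else AMBIGUOUS
    subclasses = [s for _, s in sources if s]
    subclass = Counter(subclasses).most_common(1)[0][0] if subclasses else ""
    return class_meta, subclass


# ---------------------------------------------------------------------------
# table-level driver


def annotate_features(
    meta: pd.DataFrame,
    library: Sequence[LibraryEntry],
    bin_tol: float = 0.01,
    rt_tol: float = 0.2,
    precursor_tol: float = 0.01,
    total_threshold: float = 700.0,
    dot_threshold: float = 600.0,
    sqrt_weight: bool = True,
) -> pd.DataFrame:
    """Annotate every feature in a metadata frame (columns mz, rt, ms2).

    Candidates are pre-filtered on precursor m/z within ``precursor_tol``
    Da.  Returns one row per feature with level, matched name, scores and
    class assignment (class columns empty for unannotated features).
    """
    lib_mz = np.array([e.precursor_mz for e in library])
    rows = []
    for fid, row in meta.iterrows():
        ms2 = parse_ms2(row["ms2"]) if isinstance(row["ms2"], str) else list(row["ms2"])
        cand_idx = np.flatnonzero(np.abs(lib_mz - row["mz"]) <= precursor_tol) if len(library) else []
        candidates = [library[i] for i in cand_idx]
        rec = assign_level(
            str(fid), ms2, float(row["rt"]), candidates,
            bin_tol, rt_tol, total_threshold, dot_threshold, sqrt_weight,
        )
        if rec.level in (1, 2):
            entry = next(e for e in library if e.name == rec.matched_name)
            rec.class_meta, rec.subclass = classify_feature(
                rec, [(entry.class_meta, entry.subclass)]
            )
        rows.append(
            {
                "feature_id": rec.feature_id,
                "level": rec.level,
                "matched_name": rec.matched_name,
                "dot": rec.dot,
                "revdot": rec.revdot,
                "total": rec.total,
                "class_meta": rec.class_meta,
                "subclass": rec.subclass,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "level", "matched_name", "dot", "revdot", "total",
                 "class_meta", "subclass"],
    ).set_index("feature_id")


def class_counts(annotations: pd.DataFrame) -> dict[str, int]:
    """Environmental / endogenous / ambiguous counts over annotated features."""
    annotated = annotations[annotations["level"].isin([1, 2])]
    counts = annotated["class_meta"].value_counts().to_dict()
    return {
        ENVIRONMENTAL: int(counts.get(ENVIRONMENTAL, 0)),
        ENDOGENOUS: int(counts.get(ENDOGENOUS, 0)),
        AMBIGUOUS: int(counts.get(AMBIGUOUS, 0)),
    }


# ---------------------------------------------------------------------------
# library I/O (MSP / MGF via matchms)


def load_library(path: str | Path) -> list[LibraryEntry]:
    """Load a spectral library from MSP or MGF."""
    from matchms.importing import load_from_mgf, load_from_msp

    path = Path(path)
    loader = load_from_mgf if path.suffix.lower() == ".mgf" else load_from_msp
    entries = []
    for spec in loader(str(path), metadata_harmonization=False):
        md = spec.metadata
        rt = md.get("retention_time")
        entries.append(
            LibraryEntry(
                name=str(md.get("compound_name", md.get("name", ""))),
                precursor_mz=float(md.get("precursor_mz", 0.0)),
                ms2=tuple(zip(spec.peaks.mz.tolist(), spec.peaks.intensities.tolist())),
                rt=float(rt) if rt not in (None, "") else None,
                class_meta=str(md.get("class_meta", AMBIGUOUS)),
                subclass=str(md.get("subclass", "")),
            )
        )
    return entries


def save_library(entries: Sequence[LibraryEntry], path: str | Path) -> None:
    """Write a spectral library as MSP."""
    from matchms import Spectrum
    from matchms.exporting import save_as_msp

    spectra = []
    for e in entries:
        mz = np.array([p[0] for p in e.ms2], dtype=float)
        order = np.argsort(mz)
        inten = np.array([p[1] for p in e.ms2], dtype=float)
        metadata = {
            "compound_name": e.name,
            "precursor_mz": e.precursor_mz,
            "class_meta": e.class_meta,
            "subclass": e.subclass,
        }
        if e.rt is not None:
            metadata["retention_time"] = e.rt
        spectra.append(Spectrum(mz=mz[order], intensities=inten[order], metadata=metadata))
    path = Path(path)
    if path.exists():
        path.unlink()  # matchms appends to existing files
    save_as_msp(spectra, str(path))
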