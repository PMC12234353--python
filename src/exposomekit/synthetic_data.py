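"""Synthetic cohort and LC-HRMS raw-data generator.

Individual-level biobank data of the kind this pipeline analyzes cannot be
redistributed, so every input is emulated: a longitudinal cohort of women
with reproductive covariates (parity strata 26/23/27/24, 61 second visits
among the 74 parous women, sampling years 1987-2006, five injection
batches), targeted analyte concentrations with known generative effects
and MLOQ censoring, per-ESI-mode untargeted feature tables with planted
cross-mode duplicates, in-source fragment pairs, blank-dominated features
and batch-correlated internal-standard drift, and an MSP spectral library.

The generative law for concentrations is log-normal with linear covariate
effects on the log scale,

    log c = b0 + sum_k beta_k x_k + u_subject + eps,

which reproduces the left skew that the downstream square-root transform
targets.  Detection is deterministic: values below MLOQ/3 are non-detects,
values in [MLOQ/3, MLOQ) are detected-but-below-MLOQ.  All randomness
flows from one master seed through named child streams so each artefact
can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import LibraryEntry, format_ms2
from .feature_processing import NEGATIVE, POSITIVE, PROTON_MASS, RawFeatureTable
from .target_quant import (
    BELOW_MLOQ,
    NONDETECT,
    QUANTIFIED,
    Calibration,
    ConcentrationMatrix,
    fit_calibration,
)

#: deterministic censoring boundary between non-detect and below-MLOQ
NONDETECT_FRACTION = 1.0 / 3.0

#: default parity strata (no pregnancy, 1-2, 3-4, >4) for 100 women
DEFAULT_STRATA = (26, 23, 27, 24)
#: second blood samples provided per stratum (nullipara give one sample)
DEFAULT_SECOND_SAMPLES = (0, 22, 21, 18)

#: per-stratum cohort parameters: age at first/second sample (mean, SD),
#: first/second sampling-year range, BMI (mean, SD), P(ever tobacco),
#: P(ever hormonal contraception), P(ever hormone therapy)
DEFAULT_STRATUM_PARAMS: tuple[dict, ...] = (
    dict(age1=(58.28, 6.48), age2=None, years1=(1995, 2006), years2=None,
         bmi=(25.36, 4.03), tobacco=0.154, contraception=0.423, hrt=0.174,
         pregnancies=(0, 0)),
    dict(age1=(34.77, 5.33), age2=(43.58, 4.13), years1=(1987, 2005), years2=(1997, 2006),
         bmi=(23.07, 2.91), tobacco=0.522, contraception=0.957, hrt=0.167,
         pregnancies=(1, 2)),
    dict(age1=(39.99, 4.72), age2=(46.35, 3.98), years1=(1988, 2006), years2=(2000, 2006),
         bmi=(25.02, 5.38), tobacco=0.407, contraception=0.808, hrt=0.080,
         pregnancies=(3, 4)),
    dict(age1=(40.36, 3.09), age2=(47.16, 4.83), years1=(1988, 2002), years2=(1996, 2006),
         bmi=(24.59, 3.75), tobacco=0.458, contraception=0.875, hrt=0.125,
         pregnancies=(5, 7)),
)

MENARCHE_MEAN = 13.0
MENARCHE_SD = 1.3
MENARCHE_MISSING_P = 0.01
SAMPLE_YEAR_RANGE = (1987, 2006)
N_BATCHES = 5
MAX_VISIT_GAP_YEARS = 16


def child_seed(master_seed: int, stream: str) -> np.random.Generator:
    """Derive an independent named random stream from the master seed."""
    import zlib

    ss = np.random.SeedSequence([master_seed, zlib.crc32(stream.encode()) % (2**31)])
    return np.random.default_rng(ss)


def _stream(master_seed: int, index: int) -> np.random.Generator:
    # counter scheme: child i of master seed s is SeedSequence([s, i])
    return np.random.default_rng(np.random.SeedSequence([master_seed, index]))


@dataclass
class Cohort:
    """Participants and their sampling visits.

    ``participants``: one row per woman (index id) with birth_year,
    n_pregnancies, n_deliveries, age_menarche (nullable), bmi,
    tobacco_ever, hormonal_contraception_ever, hrt_ever, parity_stratum,
    last_pregnancy_year.  ``samples``: one row per visit (index sample id)
    with participant_id, visit, age_at_sampling, sample_year, batch.
    """

    participants: pd.DataFrame
    samples: pd.DataFrame

    @property
    def n_women(self) -> int:
        return len(self.participants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def covariate_frame(self) -> pd.DataFrame:
        """Per-sample modelling frame: exposures + adjustment covariates."""
        s = self.samples
        p = self.participants.loc[s["participant_id"]]
        return pd.DataFrame(
            {
                "participant_id": s["participant_id"].to_numpy(),
                "visit": s["visit"].to_numpy(),
                "age": s["age_at_sampling"].to_numpy(dtype=float),
                "sample_year": s["sample_year"].to_numpy(dtype=float),
                "batch": s["batch"].to_numpy(),
                "birth_year": p["birth_year"].to_numpy(dtype=float),
                "n_pregnancies": p["n_pregnancies"].to_numpy(dtype=float),
                "n_deliveries": p["n_deliveries"].to_numpy(dtype=float),
                "age_menarche": p["age_menarche"].to_numpy(dtype=float),
                "bmi": p["bmi"].to_numpy(dtype=float),
                "tobacco_ever": p["tobacco_ever"].to_numpy(dtype=float),
            },
            index=s.index,
        )

    def write(self, samples_path, participants_path) -> None:
        self.samples.to_csv(samples_path, sep="\t")
        self.participants.to_csv(participants_path, sep="\t")


def read_cohort(samples_path, participants_path) -> Cohort:
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    participants = pd.read_csv(participants_path, sep="\t", index_col=0)
    return Cohort(participants, samples)


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    n_women: int = 100,
    strata_counts: Sequence[int] = DEFAULT_STRATA,
    second_sample_counts: Sequence[int] = DEFAULT_SECOND_SAMPLES,
    seed: int = 0,
    stratum_params: Sequence[Mapping] = DEFAULT_STRATUM_PARAMS,
) -> Cohort:
    """Generate a parity-stratified longitudinal cohort.

    Exactly ``strata_counts[i]`` women fall in parity stratum i; the first
    ``second_sample_counts[i]`` of them provide a second sample 1-16
    years after the first.  Ages, BMI and tobacco/hormone-use covariates
    are drawn from the per-stratum parameters; parous women have their
    first sample placed within two years of their last pregnancy
    (mirroring the selection criterion of the emulated study design).
    """
    strata_counts = [int(c) for c in strata_counts]
    second_sample_counts = [int(c) for c in second_sample_counts]
    if len(strata_counts) != 4 or len(second_sample_counts) != 4:
        raise ValueError("four parity strata are required")
    if any(c < 0 for c in strata_counts + second_sample_counts):
        raise ValueError("stratum counts must be non-negative")
    if sum(strata_counts) != n_women:
        raise ValueError(
            f"strata counts {strata_counts} sum to {sum(strata_counts)}, not n_women={n_women}"
        )
    for i, (n, m) in enumerate(zip(strata_counts, second_sample_counts)):
        if m > n:
            raise ValueError(f"stratum {i}: second-sample count {m} exceeds stratum size {n}")
    if second_sample_counts[0] != 0:
        raise ValueError("stratum 0 (nulliparous) cannot provide second samples")

    rng = _stream(seed, 0)
    part_rows, sample_rows = [], []
    widx = 0
    for stratum, (n_s, n_second) in enumerate(zip(strata_counts, second_sample_counts)):
        par = stratum_params[stratum]
        for k in range(n_s):
            widx += 1
            pid = f"W{widx:04d}"
            year1 = int(rng.integers(par["years1"][0], par["years1"][1] + 1))
            age1 = float(np.clip(rng.normal(*par["age1"]), 18.0, 75.0))
            birth_year = year1 - int(round(age1))
            lo, hi = par["pregnancies"]
            n_preg = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            # most pregnancies end in a delivery; miscarriages/terminations do not
            n_del = int(rng.binomial(n_preg, 0.85)) if n_preg else 0
            menarche = float(np.round(rng.normal(MENARCHE_MEAN, MENARCHE_SD), 1))
            if rng.random() < MENARCHE_MISSING_P:
                menarche = np.nan
            hc = bool(rng.random() < par["contraception"])
            hrt = bool(rng.random() < par["hrt"])
            last_preg = year1 - int(rng.integers(0, 3)) if n_preg else np.nan
            part_rows.append(
                dict(
                    id=pid, birth_year=birth_year, parity_stratum=stratum,
                    n_pregnancies=n_preg, n_deliveries=n_del,
                    age_menarche=menarche,
                    bmi=float(np.clip(rng.normal(*par["bmi"]), 15.0, 45.0)),
                    tobacco_ever=bool(rng.random() < par["tobacco"]),
                    hormonal_contraception_ever=hc, hrt_ever=hrt,
                    last_pregnancy_year=last_preg,
                )
            )
            sample_rows.append(
                dict(sample_id=f"{pid}_v1", participant_id=pid, visit=1,
                     age_at_sampling=year1 - birth_year, sample_year=year1)
            )
            if k < n_second:
                gap = int(rng.integers(1, MAX_VISIT_GAP_YEARS + 1))
                year2 = min(year1 + gap, SAMPLE_YEAR_RANGE[1])
                year2 = max(year2, year1)
                sample_rows.append(
                    dict(sample_id=f"{pid}_v2", participant_id=pid, visit=2,
                         age_at_sampling=year2 - birth_year, sample_year=year2)
                )
    participants = pd.DataFrame(part_rows).set_index("id") if part_rows else pd.DataFrame(
        columns=["birth_year", "parity_stratum", "n_pregnancies", "n_deliveries",
                 "age_menarche", "bmi", "tobacco_ever", "hormonal_contraception_ever",
                 "hrt_ever", "last_pregnancy_year"]
    )
    samples = pd.DataFrame(sample_rows).set_index("sample_id") if sample_rows else pd.DataFrame(
        columns=["participant_id", "visit", "age_at_sampling", "sample_year", "batch"]
    )
    if len(samples):
        # injection batches partition the run in acquisition (sampling-year) order
        order = samples.sort_values(["sample_year", "participant_id", "visit"]).index
        batch = pd.Series(0, index=order)
        for b, chunk in enumerate(np.array_split(np.arange(len(order)), N_BATCHES)):
            batch.iloc[chunk] = b + 1
        samples["batch"] = batch.reindex(samples.index)
    return Cohort(participants, samples)


# ---------------------------------------------------------------------------
# targeted concentrations


@dataclass(frozen=True)
class EffectSpec:
    """Generative parameters for one analyte on the log-concentration scale."""

    baseline_log_mean: float
    coefficients: Mapping[str, float] = field(default_factory=dict)
    subject_sd: float = 0.3
    residual_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for name, value in self.coefficients.items():
            if not np.isfinite(value):
                raise ValueError(f"coefficient on {name!r} is not finite")


#: covariates an EffectSpec may act on (values taken from Cohort.covariate_frame)
EFFECT_COVARIATES = ("age", "n_pregnancies", "n_deliveries", "age_menarche", "sample_year")

#: covariate centering used when composing the log-scale linear predictor,
#: so baselines stay interpretable as typical log concentrations
_COVARIATE_CENTER = {"age": 43.0, "n_pregnancies": 2.4, "n_deliveries": 2.0,
                     "age_menarche": 13.0, "sample_year": 1997.0}


def generate_target_truth(
    cohort: Cohort,
    effects: Mapping[str, EffectSpec],
    mloqs: Mapping[str, float],
    seed: int = 0,
    analyte_class: Mapping[str, str] | None = None,
) -> tuple[ConcentrationMatrix, dict]:
    """Simulate true concentrations and their censored observation.

    Returns the observed :class:`ConcentrationMatrix` (statuses assigned by
    deterministic MLOQ thresholding: < MLOQ/3 non-detect, < MLOQ
    below-MLOQ) plus a latent-truth record (true concentrations, subject
    intercepts and the effect specs) for parameter-recovery tests.
    """
    for a, m in mloqs.items():
        if m <= 0:
            raise ValueError(f"MLOQ for {a!r} must be > 0")
    for a, eff in effects.items():
        unknown = set(eff.coefficients) - set(EFFECT_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates in effect spec for {a!r}: {sorted(unknown)}")
    rng = _stream(seed, 1)
    cov = cohort.covariate_frame()
    # missing covariate values enter the generative predictor at their center
    analytes = list(effects)
    n = len(cov)
    values = pd.DataFrame(0.0, index=analytes, columns=cov.index)
    truth_conc = values.copy()
    status = pd.DataFrame(NONDETECT, index=analytes, columns=cov.index)
    intercepts = {}
    subjects = cov["participant_id"].to_numpy()
    unique_subjects = list(dict.fromkeys(subjects))
    for a in analytes:
        eff = effects[a]
        lin = np.full(n, eff.baseline_log_mean)
        for name, beta in eff.coefficients.items():
            x = cov[name].to_numpy(dtype=float)
            x = np.where(np.isnan(x), _COVARIATE_CENTER[name], x)
            lin = lin + beta * (x - _COVARIATE_CENTER[name])
        u = {s: rng.normal(0.0, eff.subject_sd) for s in unique_subjects}
        lin = lin + np.array([u[s] for s in subjects])
        lin = lin + rng.normal(0.0, eff.residual_sd, size=n)
        conc = np.exp(lin)
        truth_conc.loc[a] = conc
        mloq = float(mloqs[a])
        st = np.where(conc < mloq * NONDETECT_FRACTION, NONDETECT,
                      np.where(conc < mloq, BELOW_MLOQ, QUANTIFIED))
        observed = np.where(st == NONDETECT, 0.0, conc)
        values.loc[a] = observed
        status.loc[a] = st
        intercepts[a] = u
    matrix = ConcentrationMatrix(
        values, status,
        pd.Series({a: float(mloqs[a]) for a in analytes}),
        pd.Series({a: (analyte_class or {}).get(a, "unknown") for a in analytes}),
    )
    truth = {"concentrations": truth_conc, "intercepts": intercepts, "effects": dict(effects)}
    return matrix, truth


# default targeted panel --------------------------------------------------

#: log-scale effect directions: chemical burden accumulates with age for
#: persistent compounds and is eliminated through pregnancies/deliveries
_PFAS_EFFECT = dict(age=0.02, n_pregnancies=-0.08)


def default_target_panel() -> tuple[dict[str, EffectSpec], dict[str, float], dict[str, str]]:
    """Effect specs, MLOQs (ng/mL) and class labels for the default panel.

    Baselines roughly track the published mean plasma levels of each
    compound class; PFAS carry positive age and negative parity effects,
    precursor PFAS a positive menarche effect, caffeine a positive age
    effect.  Linear/branched pairs are generated separately and summed
    downstream.
    """
    specs: dict[str, EffectSpec] = {}
    mloq: dict[str, float] = {}
    cls: dict[str, str] = {}

    def add(name, base, coefs, m, c, subject_sd=0.35, residual_sd=0.3):
        specs[name] = EffectSpec(base, coefs, subject_sd, residual_sd)
        mloq[name] = m
        cls[name] = c

    for fam, base in [("PFOS", 2.2), ("PFHxS", -0.6), ("PFHpS", -1.7), ("PFOA", 0.5),
                      ("FOSA", -1.1)]:
        add(f"{fam}_linear", base, _PFAS_EFFECT, 0.05, "PFAS")
        add(f"{fam}_branched", base - 1.2, _PFAS_EFFECT, 0.05, "PFAS")
    add("PFNA", -0.9, _PFAS_EFFECT, 0.05, "PFAS")
    add("PFDA", -1.8, _PFAS_EFFECT, 0.05, "PFAS")
    add("PFUnDA", -1.7, _PFAS_EFFECT, 0.05, "PFAS")
    add("PFHpA", -3.0, _PFAS_EFFECT, 0.04, "PFAS")
    for prec, base in [("FOSAA", -0.1), ("NMeFOSAA", -0.9), ("NEtFOSAA", 0.0)]:
        add(prec, base, dict(age=-0.005, age_menarche=0.05, sample_year=-0.04), 0.1, "PFAS")
    add("Caffeine", 5.1, dict(age=0.02), 2.0, "food", residual_sd=0.9)
    add("Cotinine", 1.0, dict(), 0.5, "tobacco", residual_sd=2.0)
    add("Progesterone", 0.3, dict(), 0.2, "steroid hormone", residual_sd=1.8)
    add("Testosterone", -1.8, dict(), 0.05, "steroid hormone")
    add("Hydrocortisone", 5.0, dict(), 5.0, "steroid hormone")
    add("Corticosterone", 1.7, dict(), 0.5, "steroid hormone")
    add("Pentachlorophenol", 0.5, dict(sample_year=-0.05), 0.3, "fungicide")
    add("TCPy", -1.2, dict(sample_year=0.04), 0.1, "insecticide")
    return specs, mloq, cls


# targeted raw artefacts ---------------------------------------------------

DEFAULT_CAL_LEVELS = (0.01, 0.025, 0.1, 0.25, 1.0, 2.5, 10.0, 25.0, 100.0)


def generate_calibration_tables(
    analytes: Sequence[str],
    seed: int = 0,
    levels: Sequence[float] = DEFAULT_CAL_LEVELS,
    n_batches: int = N_BATCHES,
    n_injections: int = 3,
    noise_sd: float = 0.01,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-batch replicate calibration injections for each analyte.

    Returns a tidy table (analyte, batch, injection, concentration,
    response_ratio) and the true slopes used, for round-trip checks.
    True response curves are linear through the origin with per-analyte
    slopes; each injection adds i.i.d. ratio noise.
    """
    rng = _stream(seed, 2)
    slopes = {a: float(rng.uniform(0.2, 2.0)) for a in analytes}
    rows = []
    for a in analytes:
        for b in range(1, n_batches + 1):
            for inj in range(1, n_injections + 1):
                for c in levels:
                    ratio = slopes[a] * c + rng.normal(0.0, noise_sd)
                    rows.append(
                        dict(analyte=a, batch=b, injection=inj,
                             concentration=c, response_ratio=ratio)
                    )
    return pd.DataFrame(rows), slopes


def calibrations_from_table(table: pd.DataFrame) -> dict[tuple[str, int], Calibration]:
    """Fit one averaged calibration per (analyte, batch) from replicate injections."""
    from .target_quant import average_calibrations

    out: dict[tuple[str, int], Calibration] = {}
    for (a, b), grp in table.groupby(["analyte", "batch"]):
        cals = [
            fit_calibration(
                list(zip(inj_grp["concentration"], inj_grp["response_ratio"])), analyte=a
            )
            for _, inj_grp in grp.groupby("injection")
        ]
        out[(a, b)] = average_calibrations(cals)
    return out


def generate_target_areas(
    matrix: ConcentrationMatrix,
    true_slopes: Mapping[str, float],
    seed: int = 0,
    is_area: float = 1.0e6,
    area_noise_sd: float = 0.005,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn true concentrations into instrument peak areas.

    Areas follow the true response line (ratio = slope * concentration)
    with small multiplicative noise; censored non-detect cells have no
    integrable peak (area 0).  Returns (areas, internal-standard areas).
    """
    rng = _stream(seed, 3)
    areas = pd.DataFrame(0.0, index=matrix.analytes, columns=matrix.samples)
    is_areas = pd.DataFrame(is_area, index=matrix.analytes, columns=matrix.samples)
    for a in matrix.analytes:
        slope = float(true_slopes[a])
        conc = matrix.values.loc[a].to_numpy(dtype=float)
        ratio = slope * conc * np.exp(rng.normal(0.0, area_noise_sd, size=len(conc)))
        areas.loc[a] = ratio * is_area
    areas[matrix.status == NONDETECT] = 0.0
    return areas, is_areas


# ---------------------------------------------------------------------------
# untargeted feature tables


@dataclass
class PlantingPlan:
    """What structure to plant into the untargeted tables.

    Cross-mode duplicate pairs share a neutral mass within the merge
    tolerance; in-source fragment pairs co-elute (RT within 0.1 min) with
    near-perfectly correlated areas; blank features carry signal only in
    the procedural blanks; a stated fraction of ordinary features is
    sporadic (detection frequency below the 70% gate).  Internal-standard
    and feature intensities share a per-batch multiplicative drift so the
    IS-PCA normalization has signal to remove.
    """

    n_cross_mode_pairs: int = 4
    n_insource_pairs: int = 4
    n_blank_features: int = 4
    n_internal_standards: int = 34
    n_blanks_per_batch: int = 2
    n_qc_per_batch: int = 1
    batch_drift_sd: float = 0.15
    mean_log_area: float = 13.3  # ln scale; exp(13.3) ~ 6e5
    log_area_sd: float = 0.8
    residual_sd: float = 0.25
    sporadic_fraction: float = 0.25
    mz_jitter: float = 0.0005  # Da, must stay within the 0.002 Da merge tolerance
    rt_jitter: float = 0.02  # min, must stay within the merge/dedup RT tolerances
    library_fraction: float = 0.3  # fraction of library entries planted as features
    age_effect_fraction: float = 0.1
    age_effect: float = 0.02


def _ms2_spectrum(rng: np.random.Generator, precursor: float, n_peaks: int = 6):
    mz = np.sort(rng.uniform(50.0, max(60.0, precursor - 1.0), size=n_peaks))
    inten = rng.uniform(5.0, 100.0, size=n_peaks)
    return list(zip(mz.tolist(), inten.tolist()))


def generate_spectral_library(
    n_entries: int = 40,
    seed: int = 0,
    inhouse_fraction: float = 0.3,
    class_probs: Mapping[str, float] | None = None,
) -> list[LibraryEntry]:
    """Synthetic MSP-style spectral library with class/subclass metadata."""
    from .annotation import AMBIGUOUS, ENDOGENOUS, ENVIRONMENTAL

    probs = class_probs or {ENVIRONMENTAL: 0.57, ENDOGENOUS: 0.39, AMBIGUOUS: 0.04}
    subclasses = {
        ENVIRONMENTAL: ["PFAS", "pesticides", "dietary", "industrial", "personal care"],
        ENDOGENOUS: ["fatty acids", "bile acids", "hormones", "amino acids"],
        AMBIGUOUS: ["mixed-source"],
    }
    rng = _stream(seed, 4)
    entries = []
    for i in range(n_entries):
        precursor = float(rng.uniform(120.0, 750.0))
        cls = rng.choice(list(probs), p=np.array(list(probs.values())) / sum(probs.values()))
        entries.append(
            LibraryEntry(
                name=f"LIB{i:04d}",
                precursor_mz=precursor,
                ms2=tuple(_ms2_spectrum(rng, precursor)),
                rt=float(rng.uniform(0.5, 14.0)) if rng.random() < inhouse_fraction else None,
                class_meta=str(cls),
                subclass=str(rng.choice(subclasses[str(cls)])),
            )
        )
    return entries


def generate_untargeted_tables(
    cohort: Cohort,
    n_features: Mapping[str, int] | None = None,
    planting: PlantingPlan | None = None,
    seed: int = 0,
    library: Sequence[LibraryEntry] | None = None,
) -> tuple[RawFeatureTable, RawFeatureTable, pd.DataFrame]:
    """Generate ESI+ and ESI- aligned feature tables plus the IS matrix.

    Planted structure (cross-mode duplicates, in-source fragments,
    blank-dominated features, library spectra) is validated against its
    own tolerances at generation time.  Returns (positive table, negative
    table, internal-standard matrix over the study samples).
    """
    plan = planting or PlantingPlan()
    n_features = dict(n_features or {"pos": 120, "neg": 90})
    rng = _stream(seed, 5)
    samples = list(cohort.samples.index)
    batches = cohort.samples["batch"].to_dict() if len(cohort.samples) else {}
    batch_ids = sorted(set(batches.values())) or [1]
    blank_cols = [f"blank_b{b}_{i+1}" for b in batch_ids for i in range(plan.n_blanks_per_batch)]
    qc_cols = [f"QC_b{b}_{i+1}" for b in batch_ids for i in range(plan.n_qc_per_batch)]

    # per-sample instrumental drift, correlated within injection batch
    batch_drift = {b: rng.normal(0.0, plan.batch_drift_sd) for b in batch_ids}
    drift = {s: batch_drift[batches[s]] + rng.normal(0.0, 0.02) for s in samples}

    ages = cohort.samples["age_at_sampling"].to_numpy(dtype=float) if samples else np.array([])

    def sample_areas(mu: float, sporadic: bool, age_beta: float = 0.0) -> np.ndarray:
        lin = mu + np.array([drift[s] for s in samples]) + rng.normal(
            0.0, plan.residual_sd, size=len(samples)
        )
        if age_beta and len(ages):
            lin = lin + age_beta * (ages - 43.0)
        areas = np.exp(lin)
        if sporadic:
            detect_p = rng.uniform(0.15, 0.65)
        else:
            detect_p = rng.uniform(0.9, 1.0)
        detected = rng.random(len(samples)) < detect_p
        return np.where(detected, areas, 0.0)

    tables: dict[str, dict] = {}
    for mode_key, mode in (("pos", POSITIVE), ("neg", NEGATIVE)):
        n = int(n_features.get(mode_key, 0))
        rows_meta, rows_areas = [], []
        lib_planted = 0
        lib_entries = [e for e in (library or [])]
        n_lib = int(len(lib_entries) * plan.library_fraction) if mode_key == "pos" else 0
        for i in range(n):
            fid = f"{mode_key.upper()}{i:05d}"
            entry = None
            if lib_planted < n_lib:
                entry = lib_entries[lib_planted]
                lib_planted += 1
            if entry is not None:
                mz = entry.precursor_mz + rng.normal(0.0, plan.mz_jitter / 2)
                rt = (entry.rt if entry.rt is not None else float(rng.uniform(0.5, 14.0)))
                rt += rng.normal(0.0, plan.rt_jitter / 2)
                ms2 = [(m + rng.normal(0.0, 0.001), it * rng.uniform(0.9, 1.1))
                       for m, it in entry.ms2]
            else:
                mz = float(rng.uniform(80.0, 800.0))
                rt = float(rng.uniform(0.3, 15.0))
                ms2 = _ms2_spectrum(rng, mz)
            mu = rng.normal(plan.mean_log_area, plan.log_area_sd)
            sporadic = rng.random() < plan.sporadic_fraction
            age_beta = plan.age_effect if rng.random() < plan.age_effect_fraction else 0.0
            s_areas = sample_areas(mu, sporadic, age_beta)
            b_areas = np.exp(rng.normal(plan.mean_log_area - 5.0, 0.5, size=len(blank_cols)))
            q_areas = np.exp(mu + rng.normal(0.0, 0.05, size=len(qc_cols)))
            rows_meta.append(dict(feature_id=fid, mz=mz, rt=rt, mode=mode, ms2=format_ms2(ms2)))
            rows_areas.append(np.concatenate([s_areas, b_areas, q_areas]))
        tables[mode_key] = dict(meta=rows_meta, areas=rows_areas)

    def append_feature(mode_key, fid, mz, rt, ms2, s_areas, b_areas=None, q_areas=None):
        mode = POSITIVE if mode_key == "pos" else NEGATIVE
        if b_areas is None:
            b_areas = np.exp(rng.normal(plan.mean_log_area - 5.0, 0.5, size=len(blank_cols)))
        if q_areas is None:
            q_areas = np.full(len(qc_cols), max(float(np.mean(s_areas[s_areas > 0])) if
                                                np.any(s_areas > 0) else 0.0, 0.0))
        tables[mode_key]["meta"].append(
            dict(feature_id=fid, mz=mz, rt=rt, mode=mode, ms2=format_ms2(ms2)))
        tables[mode_key]["areas"].append(np.concatenate([s_areas, b_areas, q_areas]))

    # planted cross-mode duplicates: same neutral molecule seen as
    # [M+H]+ and [M-H]-; the lower-intensity member should merge away
    for i in range(plan.n_cross_mode_pairs):
        neutral = float(rng.uniform(150.0, 600.0))
        rt = float(rng.uniform(1.0, 14.0))
        mz_pos = neutral + PROTON_MASS + rng.normal(0.0, plan.mz_jitter / 4)
        mz_neg = neutral - PROTON_MASS + rng.normal(0.0, plan.mz_jitter / 4)
        rt_neg = rt + rng.normal(0.0, plan.rt_jitter / 2)
        d_mass = abs((mz_pos - PROTON_MASS) - (mz_neg + PROTON_MASS))
        if d_mass > 0.002 or abs(rt - rt_neg) > 0.2:
            raise ValueError(
                f"planted cross-mode pair {i} violates its own tolerance "
                f"(dM={d_mass:.5f} Da, dRT={abs(rt - rt_neg):.3f} min)"
            )
        mu = rng.normal(plan.mean_log_area + 0.5, 0.3)
        base = sample_areas(mu, sporadic=False)
        ms2 = _ms2_spectrum(rng, mz_pos)
        append_feature("pos", f"XPOS{i:03d}", mz_pos, rt, ms2, base)
        append_feature("neg", f"XNEG{i:03d}", mz_neg, rt_neg,
                       _ms2_spectrum(rng, mz_neg), base * 0.5)

    # planted in-source fragment pairs: co-eluting, near-perfect correlation
    for i in range(plan.n_insource_pairs):
        mz = float(rng.uniform(200.0, 700.0))
        rt = float(rng.uniform(1.0, 14.0))
        mu = rng.normal(plan.mean_log_area + 0.5, 0.3)
        parent = sample_areas(mu, sporadic=False)
        frag = parent * 0.4 * np.exp(rng.normal(0.0, 0.01, size=len(parent)))
        rt_frag = rt + rng.normal(0.0, plan.rt_jitter / 2)
        if abs(rt - rt_frag) > 0.1:
            raise ValueError(f"planted in-source pair {i} violates the 0.1 min RT tolerance")
        append_feature("pos", f"ISRC{i:03d}A", mz, rt, _ms2_spectrum(rng, mz), parent)
        append_feature("pos", f"ISRC{i:03d}B", mz - 44.998, rt_frag,
                       _ms2_spectrum(rng, mz - 44.998), frag)

    # blank-dominated features: contamination, signal mostly in blanks
    for i in range(plan.n_blank_features):
        mz = float(rng.uniform(80.0, 800.0))
        rt = float(rng.uniform(0.3, 15.0))
        b_areas = np.exp(rng.normal(plan.mean_log_area, 0.3, size=len(blank_cols)))
        s_areas = np.exp(rng.normal(plan.mean_log_area - 1.2, 0.3, size=len(samples)))
        append_feature("pos", f"BLNK{i:03d}", mz, rt, _ms2_spectrum(rng, mz),
                       s_areas, b_areas=b_areas)

    out_tables = {}
    for mode_key in ("pos", "neg"):
        meta = pd.DataFrame(tables[mode_key]["meta"],
                            columns=["feature_id", "mz", "rt", "mode", "ms2"])
        meta = meta.set_index("feature_id")
        cols = samples + blank_cols + qc_cols
        if tables[mode_key]["areas"]:
            areas = pd.DataFrame(tables[mode_key]["areas"], index=meta.index, columns=cols)
        else:
            areas = pd.DataFrame(np.zeros((0, len(cols))), index=meta.index, columns=cols)
        out_tables[mode_key] = RawFeatureTable(meta, areas, list(samples),
                                               list(blank_cols), list(qc_cols))

    # isotope-labeled internal standards: constant true level, batch drift
    is_rows = {}
    for i in range(plan.n_internal_standards):
        base = rng.normal(plan.mean_log_area + 0.7, 0.2)
        is_rows[f"IS{i:02d}"] = {
            s: float(np.exp(base + drift[s] + rng.normal(0.0, 0.03))) for s in samples
        }
    is_matrix = pd.DataFrame(is_rows).T
    is_matrix = is_matrix.reindex(columns=samples) if samples else pd.DataFrame(is_rows).T
    return out_tables["pos"], out_tables["neg"], is_matrix
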