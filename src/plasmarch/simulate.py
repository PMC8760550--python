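"""Synthetic cohort and bead-array data generator.

Emulates the structure of a prospective 1:2 age/site-matched breast-cancer
case-control study assayed on antibody suspension bead arrays: log-normal
MFI readouts, per-sample dilution factors, per-plate batch effects,
duplicated (replicate) samples, individuals sampled twice ("doubles"),
planted archetype structure on the probability simplex, linear covariate
effects (BMI, age, entry date), a menopausal-hormone-therapy protein
signature, and deliberately defective antibodies of the three kinds the
QC stage must catch.

Everything is planted at the log-intensity level; no attempt is made to
model bead chemistry (counts, saturation). The ground truth of every
planted parameter is returned in :class:`SimulationTruth` so downstream
stages can be tested for recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import MFIMatrix

# Cohort-level constants: marginal distributions mirror a middle-aged
# Swedish mammography-screening population (ages 39-81, mean ~60;
# BMI ~25.6 +/- 4.2; four sampling sites of very unequal size; ~76%
# postmenopausal; MHT never/before/current roughly 47/39/13%).
SITES = ("site_1", "site_2", "site_3", "site_4")
SITE_PROBS = (0.515, 0.042, 0.036, 0.407)
AGE_MEAN, AGE_SD, AGE_MIN, AGE_MAX = 59.6, 9.3, 39.0, 81.0
BMI_MEAN, BMI_SD = 25.6, 4.2
ENTRY_WINDOW_DAYS = 600  # ~Jan 2011 - Sep 2012 sampling window
PLATE_SIZE = 96
POOLS_PER_PLATE = 4


@dataclass
class SampleRecord:
    """One assayed sample with its clinical annotation and plate position."""

    sample_id: str
    subject_id: str
    role: str  # study | replicate | double | pool
    case_status: str  # case | control | none
    match_set_id: str | None
    age: float
    bmi: float
    entry_date: int
    site: str
    menopausal: str  # pre | post | missing
    mht_status: str  # never | before | current | missing
    statin_status: str  # never | before | current | missing
    dense_area: float  # cm^2, nan = missing
    smoking: float  # pack-years, nan = missing
    alcohol: float  # g/week, nan = missing
    parity: str  # never | ever | missing
    prs: float  # unitless, nan = missing
    plate_id: str = ""
    well_id: str = ""


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study conditions.

    Counts mirror the emulated cohort (183 cases, 1:2 controls, 30
    doubles, 48 replicate pairs, 1073 antibodies of which roughly a
    third share a target with another antibody, five planted
    archetypes). Effect sizes are in log-MFI units; ``archetype_separation``
    is expressed as a multiple of ``noise_sd``.
    """

    n_cases: int = 183
    n_doubles: int = 30
    n_replicate_pairs: int = 48
    n_antibodies: int = 1073
    n_duplicate_targets: int = 372  # antibodies sharing a target with another
    n_planted_archetypes: int = 5
    archetype_separation: float = 4.0
    frac_mht_signature_proteins: float = 0.2
    mht_effect_size: float = 0.5
    covariate_effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {"bmi": 0.05, "age": 0.08, "entry_date": 0.03}
    )
    frac_covariate_affected: Mapping[str, float] = field(
        default_factory=lambda: {"bmi": 0.55, "age": 0.75, "entry_date": 0.10}
    )
    dilution_sd: float = 0.3
    plate_effect_sd: float = 0.1
    plate_effect_intensity_slope: float = 0.0
    noise_sd: float = 0.1
    subject_bio_sd: float = 0.25  # inter-individual set-points beyond archetypes
    double_drift_sd: float = 0.3
    case_effect_size: float = 0.0
    n_case_effect_proteins: int = 0
    n_bad_reproducibility: int = 0
    n_igg_correlated: int = 0
    n_high_background: int = 0
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "bmi": 0.007,
            "menopausal": 0.002,
            "mht_status": 0.013,
            "statin_status": 0.32,
            "dense_area": 0.036,
            "smoking": 0.005,
            "alcohol": 0.004,
            "parity": 0.002,
            "prs": 0.0,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for name in ("n_doubles", "n_replicate_pairs", "n_antibodies",
                     "n_duplicate_targets", "n_bad_reproducibility",
                     "n_igg_correlated", "n_high_background",
                     "n_case_effect_proteins"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_planted_archetypes < 1:
            raise ValueError("n_planted_archetypes must be >= 1")
        if not 0 <= self.frac_mht_signature_proteins <= 1:
            raise ValueError("frac_mht_signature_proteins must be in [0,1]")
        n_defect = (self.n_bad_reproducibility + self.n_igg_correlated
                    + self.n_high_background)
        if n_defect > self.n_antibodies:
            raise ValueError("more defective antibodies requested than n_antibodies")
        if self.n_duplicate_targets + n_defect > self.n_antibodies:
            raise ValueError("duplicate targets plus defects exceed n_antibodies")


@dataclass
class SimulationTruth:
    """Planted parameters; the oracle for recovery tests."""

    baseline: np.ndarray  # (p,) log-MFI intercepts
    archetypes: np.ndarray  # (k, p) absolute log-MFI archetype rows
    archetype_deviation: np.ndarray  # (k, p) deviation from baseline
    alpha: pd.DataFrame  # per sample simplex coefficients
    labels: pd.Series  # argmax archetype per sample, 1-based
    dilutions: pd.Series  # per-sample log scaling factor
    plate_effects: pd.DataFrame  # plate x antibody log offsets
    covariate_slopes: pd.DataFrame  # antibody x {bmi, age, entry_date}
    mht_proteins: list
    mht_effects: pd.Series  # per-antibody MHT ever-user log effect
    case_proteins: list
    defects: pd.Series  # antibody -> "" | bad_reproducibility | igg_correlated | high_background
    true_covariates: pd.DataFrame  # unmasked per-sample covariates used in the model
    config: SimulationConfig


def records_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _truncnorm(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _draw_covariates(rng, n, ages=None):
    """Shared clinical covariates for n subjects."""
    age = _truncnorm(rng, AGE_MEAN, AGE_SD, AGE_MIN, AGE_MAX, n) if ages is None else ages
    bmi = np.exp(rng.normal(np.log(BMI_MEAN) - 0.5 * (BMI_SD / BMI_MEAN) ** 2,
                            BMI_SD / BMI_MEAN, n))
    post = rng.random(n) < np.where(age >= 51, 0.95, 0.08)
    mht = np.empty(n, dtype=object)
    pre_probs = (0.90, 0.08, 0.02)
    post_probs = (0.38, 0.465, 0.155)
    for i in range(n):
        probs = post_probs if post[i] else pre_probs
        mht[i] = rng.choice(["never", "before", "current"], p=probs)
    statin = rng.choice(["never", "before", "current"], size=n,
                        p=(0.735, 0.125, 0.14))
    dense = rng.gamma(1.27, 21.5, n)
    smoke = np.where(rng.random(n) < 0.48, 0.0, rng.gamma(0.8, 14.0, n))
    alcohol = rng.gamma(0.69, 84.0, n)
    parity = np.where(rng.random(n) < 0.856, "ever", "never")
    prs = rng.normal(0.0, 1.0, n)
    return dict(age=age, bmi=bmi, menopausal=np.where(post, "post", "pre"),
                mht_status=mht, statin_status=statin, dense_area=dense,
                smoking=smoke, alcohol=alcohol, parity=parity, prs=prs)


def generate_cohort(config: SimulationConfig) -> list[SampleRecord]:
    """Draw the full sample list: matched trios, doubles, replicates, pools.

    Controls are 1:2 matched to each case on age (within +/- 2 years)
    and sampling site; every matched trio, every double pair and every
    replicate pair is placed on a single 96-well plate, and each plate
    additionally carries four plasma-pool aliquots.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[SampleRecord] = []

    def make_record(sid, subj, role, status, mset, cov, i, entry):
        return SampleRecord(
            sample_id=sid, subject_id=subj, role=role, case_status=status,
            match_set_id=mset, age=float(cov["age"][i]), bmi=float(cov["bmi"][i]),
            entry_date=int(entry), site=str(cov["site"][i]),
            menopausal=str(cov["menopausal"][i]), mht_status=str(cov["mht_status"][i]),
            statin_status=str(cov["statin_status"][i]),
            dense_area=float(cov["dense_area"][i]), smoking=float(cov["smoking"][i]),
            alcohol=float(cov["alcohol"][i]), parity=str(cov["parity"][i]),
            prs=float(cov["prs"][i]),
        )

    # --- matched case-control trios -----------------------------------
    nc = config.n_cases
    case_cov = _draw_covariates(rng, nc)
    case_cov["site"] = rng.choice(SITES, size=nc, p=SITE_PROBS)
    case_cov["prs"] = case_cov["prs"] + 0.1  # cases slightly genetically enriched
    # controls: matched on age within 2y and same site, by construction
    ctl_ages = np.repeat(case_cov["age"], 2) + rng.uniform(-2.0, 2.0, 2 * nc)
    ctl_ages = np.clip(ctl_ages, 18.0, None)
    ctl_cov = _draw_covariates(rng, 2 * nc, ages=ctl_ages)
    ctl_cov["site"] = np.repeat(case_cov["site"], 2)

    entry_case = rng.integers(0, ENTRY_WINDOW_DAYS, nc)
    entry_ctl = rng.integers(0, ENTRY_WINDOW_DAYS, 2 * nc)
    sidx = 0
    for i in range(nc):
        mset = f"set_{i+1:04d}"
        records.append(make_record(f"S{sidx+1:05d}", f"subj_case_{i+1:04d}",
                                   "study", "case", mset, case_cov, i, entry_case[i]))
        sidx += 1
        for m in range(2):
            j = 2 * i + m
            records.append(make_record(f"S{sidx+1:05d}", f"subj_ctl_{j+1:04d}",
                                       "study", "control", mset, ctl_cov, j, entry_ctl[j]))
            sidx += 1

    # --- doubles: same individual sampled twice -----------------------
    nd = config.n_doubles
    if nd:
        dbl_cov = _draw_covariates(rng, nd)
        dbl_cov["site"] = rng.choice(SITES, size=nd, p=SITE_PROBS)
        first_entry = rng.integers(0, ENTRY_WINDOW_DAYS, nd)
        gap = rng.integers(326, 606, nd)  # ~10.7-19.9 months between draws
        for i in range(nd):
            subj = f"subj_dbl_{i+1:04d}"
            for visit, entry in ((1, first_entry[i]), (2, first_entry[i] + gap[i])):
                records.append(make_record(f"S{sidx+1:05d}", subj, "double", "none",
                                           None, dbl_cov, i, entry))
                sidx += 1

    # --- replicate pairs: one draw assayed twice ----------------------
    nr = config.n_replicate_pairs
    if nr:
        rep_cov = _draw_covariates(rng, nr)
        rep_cov["site"] = rng.choice(SITES, size=nr, p=SITE_PROBS)
        rep_entry = rng.integers(0, ENTRY_WINDOW_DAYS, nr)
        for i in range(nr):
            subj = f"subj_rep_{i+1:04d}"
            for _aliquot in (1, 2):
                records.append(make_record(f"S{sidx+1:05d}", subj, "replicate",
                                           "none", None, rep_cov, i, rep_entry[i]))
                sidx += 1

    _assign_plates(records, config, rng)
    return records


def _assign_plates(records: list[SampleRecord], config: SimulationConfig, rng) -> None:
    """Greedy bin-packing keeping trios and pairs on one plate; adds pools."""
    # group records into indivisible units
    units: list[list[SampleRecord]] = []
    by_set: dict[str, list[SampleRecord]] = {}
    by_subj: dict[str, list[SampleRecord]] = {}
    for r in records:
        if r.match_set_id is not None:
            by_set.setdefault(r.match_set_id, []).append(r)
        else:
            by_subj.setdefault(r.subject_id, []).append(r)
    units.extend(by_set.values())
    units.extend(by_subj.values())
    order = rng.permutation(len(units))
    capacity = PLATE_SIZE - POOLS_PER_PLATE
    n_slots = sum(len(u) for u in units)
    n_plates = max(1, int(np.ceil(n_slots / capacity)))
    loads = [0] * n_plates
    plate_units: list[list[list[SampleRecord]]] = [[] for _ in range(n_plates)]
    for ui in order:
        u = units[ui]
        # first plate with room; guaranteed to exist only if ceil was generous
        placed = False
        for p in np.argsort(loads):
            if loads[p] + len(u) <= capacity:
                plate_units[p].append(u)
                loads[p] += len(u)
                placed = True
                break
        if not placed:  # pragma: no cover - only if a unit exceeds capacity
            raise ValueError("matched unit larger than plate capacity")
    wells = [f"{row}{col:02d}" for row in "ABCDEFGH" for col in range(1, 13)]
    next_sid = max(int(r.sample_id[1:]) for r in records) + 1
    for p in range(n_plates):
        plate_id = f"plate_{p+1:02d}"
        w = 0
        for u in plate_units[p]:
            for r in u:
                r.plate_id = plate_id
                r.well_id = wells[w]
                w += 1
        for q in range(POOLS_PER_PLATE):
            records.append(SampleRecord(
                sample_id=f"S{next_sid:05d}", subject_id="pool",
                role="pool", case_status="none", match_set_id=None,
                age=float("nan"), bmi=float("nan"), entry_date=0, site="site_1",
                menopausal="missing", mht_status="missing",
                statin_status="missing", dense_area=float("nan"),
                smoking=float("nan"), alcohol=float("nan"), parity="missing",
                prs=float("nan"), plate_id=plate_id, well_id=wells[w]))
            next_sid += 1
            w += 1


# ---------------------------------------------------------------------------
# MFI matrix
# ---------------------------------------------------------------------------

def generate_mfi(
    cohort: list[SampleRecord], config: SimulationConfig
) -> tuple[MFIMatrix, pd.DataFrame, pd.Series, pd.Series, SimulationTruth]:
    """Generate the MFI matrix plus antibody metadata, empty-well and IgG
    profiles, and the planted truth.

    The log intensity of sample i at antibody j is

        baseline_j + sum_a alpha_ia * dev_aj + covariate terms
        + mht_j * 1[ever user] + case_j * 1[case]
        + plate(p_i, j) + dilution_i + eps_ij

    exponentiated and floored at 1.0. Replicate pair members share all
    biological terms and differ only in dilution and eps; double pair
    members additionally differ by a per-antibody biological drift and
    their own entry date.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    p = config.n_antibodies
    k = config.n_planted_archetypes
    ab_ids = [f"AB_{j+1:04d}" for j in range(p)]
    samples = records_to_frame(cohort)
    n = len(samples)

    baseline = rng.normal(6.9, 0.8, p)
    sep_sd = config.archetype_separation * config.noise_sd
    dev = rng.normal(0.0, sep_sd, (k, p)) if sep_sd > 0 else np.zeros((k, p))

    # defects: disjoint subsets, drawn from the unique-target pool so that
    # defect and duplicate-target counts compose additively
    defect = pd.Series("", index=ab_ids)
    n_defect = (config.n_bad_reproducibility + config.n_igg_correlated
                + config.n_high_background)
    n_unique = p - config.n_duplicate_targets
    pool_idx = rng.permutation(n_unique)[:n_defect]
    pos = 0
    bad_rep = [ab_ids[i] for i in pool_idx[pos:pos + config.n_bad_reproducibility]]
    pos += config.n_bad_reproducibility
    igg_cor = [ab_ids[i] for i in pool_idx[pos:pos + config.n_igg_correlated]]
    pos += config.n_igg_correlated
    high_bg = [ab_ids[i] for i in pool_idx[pos:pos + config.n_high_background]]
    defect[bad_rep] = "bad_reproducibility"
    defect[igg_cor] = "igg_correlated"
    defect[high_bg] = "high_background"

    # antibody table: unique targets first, duplicates share a target with
    # a randomly chosen non-defective unique-target antibody
    targets = [f"TG_{j+1:04d}" for j in range(n_unique)]
    clean_unique = [t for j, t in enumerate(targets) if defect[ab_ids[j]] == ""]
    dup_targets = list(rng.choice(clean_unique, size=config.n_duplicate_targets,
                                  replace=False)) if config.n_duplicate_targets else []
    all_targets = targets + dup_targets
    antibody_table = pd.DataFrame({
        "antibody_id": ab_ids,
        "target_gene": all_targets,
        "array_id": [f"array_{j % 3 + 1}" for j in range(p)],
        "planted_defect": defect.values,
    }).set_index("antibody_id", drop=False)

    # per-subject simplex coefficients (Dirichlet 0.3: mixtures plus
    # near-vertex samples); pools sit at the barycenter
    subjects = samples["subject_id"].unique()
    subj_alpha = {}
    for s in subjects:
        if s == "pool":
            subj_alpha[s] = np.full(k, 1.0 / k)
        else:
            subj_alpha[s] = rng.dirichlet(np.full(k, 0.3))
    alpha = np.vstack([subj_alpha[s] for s in samples["subject_id"]])

    # covariate slopes on standardized covariates
    cov_names = ("bmi", "age", "entry_date")
    cov_scale = {"bmi": (BMI_MEAN, BMI_SD), "age": (AGE_MEAN, AGE_SD),
                 "entry_date": (ENTRY_WINDOW_DAYS / 2, ENTRY_WINDOW_DAYS / np.sqrt(12))}
    slopes = pd.DataFrame(0.0, index=ab_ids, columns=list(cov_names))
    for c in cov_names:
        eff = float(config.covariate_effect_sizes.get(c, 0.0))
        frac = float(config.frac_covariate_affected.get(c, 0.0)) if isinstance(
            config.frac_covariate_affected, Mapping) else float(config.frac_covariate_affected)
        n_aff = int(round(frac * p))
        if eff != 0.0 and n_aff > 0:
            idx = rng.choice(p, size=n_aff, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_aff)
            slopes.iloc[idx, slopes.columns.get_loc(c)] = signs * eff

    # standardized covariate values; pools carry no covariate signal
    zcov = np.zeros((n, len(cov_names)))
    is_pool = (samples["role"] == "pool").to_numpy()
    for ci, c in enumerate(cov_names):
        mu, sd = cov_scale[c]
        vals = samples[c if c != "entry_date" else "entry_date"].to_numpy(float)
        z = (vals - mu) / sd
        z[is_pool] = 0.0
        zcov[:, ci] = z

    # MHT signature on ever-users (before or current)
    n_mht = int(round(config.frac_mht_signature_proteins * p))
    mht_effects = pd.Series(0.0, index=ab_ids)
    mht_idx = rng.choice(p, size=n_mht, replace=False) if n_mht else np.array([], int)
    if n_mht:
        mht_effects.iloc[mht_idx] = rng.choice([-1.0, 1.0], n_mht) * config.mht_effect_size
    ever = samples["mht_status"].isin(["before", "current"]).to_numpy()

    # case effect
    case_effects = np.zeros(p)
    case_idx = (rng.choice(p, size=config.n_case_effect_proteins, replace=False)
                if config.n_case_effect_proteins else np.array([], int))
    case_effects[case_idx] = config.case_effect_size
    is_case = (samples["case_status"] == "case").to_numpy()

    # plate effects, optionally intensity-coupled
    plate_ids = sorted(samples["plate_id"].unique())
    plate_eff = pd.DataFrame(
        rng.normal(0.0, config.plate_effect_sd, (len(plate_ids), p)),
        index=plate_ids, columns=ab_ids)
    if config.plate_effect_intensity_slope:
        # per-plate slope bounded by the configured magnitude so the
        # intensity axis is tilted, never flattened
        plate_slopes = rng.uniform(-1.0, 1.0, len(plate_ids))
        coupling = np.outer(plate_slopes, baseline - baseline.mean())
        plate_eff += config.plate_effect_intensity_slope * coupling

    dil = rng.normal(0.0, config.dilution_sd, n)
    eps = rng.normal(0.0, config.noise_sd, (n, p))

    # subject-level biological set-points: shared by replicate and double
    # members of a subject, zero for the plasma pool
    subj_bio = {s: (np.zeros(p) if s == "pool"
                    else rng.normal(0.0, config.subject_bio_sd, p))
                for s in subjects}
    bio = np.vstack([subj_bio[s] for s in samples["subject_id"]])

    logm = (baseline[None, :] + alpha @ dev + bio + zcov @ slopes.T.to_numpy()
            + np.outer(ever, np.ones(p)) * mht_effects.to_numpy()[None, :]
            + np.outer(is_case, case_effects)
            + plate_eff.loc[samples["plate_id"]].to_numpy()
            + dil[:, None] + eps)

    # biological drift for second member of each double pair
    dbl = samples[samples["role"] == "double"]
    for subj, grp in dbl.groupby("subject_id"):
        second = grp.sort_values("entry_date").index[1]
        drift = rng.normal(0.0, config.double_drift_sd, p)
        logm[samples.index.get_loc(second), :] += drift

    # defective antibodies
    # bad reproducibility: inflated technical noise on the second member
    # of every replicate pair
    if bad_rep:
        rep = samples[samples["role"] == "replicate"]
        cols = [samples.columns.get_loc("sample_id")]  # noqa: F841 (clarity)
        jidx = [ab_ids.index(a) for a in bad_rep]
        for subj, grp in rep.groupby("subject_id"):
            second = grp.index[1]
            i = samples.index.get_loc(second)
            logm[i, jidx] += rng.normal(0.0, 1.5, len(jidx))

    # IgG-correlated antibodies: additive load proportional to the
    # per-sample IgG level, scaled to dominate every other variance term
    log_igg = rng.normal(0.0, 1.0, n)
    igg_profile = pd.Series(np.exp(10.0 + log_igg), index=samples.index,
                            name="igg_mfi")
    if igg_cor:
        other_sd = np.sqrt((sep_sd ** 2) * 0.5 + config.noise_sd ** 2
                           + config.dilution_sd ** 2 + config.plate_effect_sd ** 2)
        lam = 3.0 * max(other_sd, 0.1)
        jidx = [ab_ids.index(a) for a in igg_cor]
        logm[:, jidx] += lam * log_igg[:, None]

    mfi = np.maximum(np.exp(logm), 1.0)
    values = pd.DataFrame(mfi, index=samples.index, columns=ab_ids)

    # empty-well buffer profile: low background except planted offenders,
    # which are set to mean + 5 sd of the study-sample MFI (linear scale)
    study_mask = (samples["role"] == "study").to_numpy()
    smean = values.values[study_mask].mean(axis=0)
    ssd = values.values[study_mask].std(axis=0, ddof=1)
    empty = pd.Series(np.exp(baseline - 3.0), index=ab_ids, name="empty_mfi")
    if high_bg:
        jidx = [ab_ids.index(a) for a in high_bg]
        empty.iloc[jidx] = smean[jidx] + 5.0 * ssd[jidx]

    matrix = MFIMatrix(values, samples["plate_id"], samples["role"])
    labels = pd.Series(np.argmax(alpha, axis=1) + 1, index=samples.index,
                       name="true_cluster")
    truth = SimulationTruth(
        baseline=baseline,
        archetypes=baseline[None, :] + dev,
        archetype_deviation=dev,
        alpha=pd.DataFrame(alpha, index=samples.index,
                           columns=[f"arch_{a+1}" for a in range(k)]),
        labels=labels,
        dilutions=pd.Series(dil, index=samples.index, name="log_dilution"),
        plate_effects=plate_eff,
        covariate_slopes=slopes,
        mht_proteins=[ab_ids[j] for j in mht_idx],
        mht_effects=mht_effects,
        case_proteins=[ab_ids[j] for j in case_idx],
        defects=defect,
        true_covariates=pd.DataFrame(zcov, index=samples.index,
                                     columns=list(cov_names)),
        config=config,
    )
    return matrix, antibody_table, empty, igg_profile, truth


def simulate_dataset(config: SimulationConfig):
    """Cohort + MFI in one call; returns (records, matrix, antibody_table,
    empty, igg, truth)."""
    records = generate_cohort(config)
    matrix, ab, empty, igg, truth = generate_mfi(records, config)
    return records, matrix, ab, empty, igg, truth


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_dataset(outdir, records, matrix, antibody_table, empty, igg, truth):
    """Write samples.csv, mfi.csv, antibodies.csv, empty_wells.csv, igg.csv
    and truth.json (full double precision)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(outdir / "samples.csv", index=False)
    m = matrix.values.copy()
    m.insert(0, "sample_id", m.index)
    m.to_csv(outdir / "mfi.csv", index=False, float_format="%.17g")
    antibody_table.to_csv(outdir / "antibodies.csv", index=False)
    empty.rename_axis("antibody_id").reset_index().to_csv(
        outdir / "empty_wells.csv", index=False, float_format="%.17g")
    igg.rename_axis("sample_id").reset_index().to_csv(
        outdir / "igg.csv", index=False, float_format="%.17g")
    t = {
        "baseline": truth.baseline.tolist(),
        "archetypes": truth.archetypes.tolist(),
        "alpha": truth.alpha.values.tolist(),
        "labels": truth.labels.tolist(),
        "dilutions": truth.dilutions.tolist(),
        "covariate_slopes": truth.covariate_slopes.to_dict(orient="list"),
        "mht_proteins": truth.mht_proteins,
        "case_proteins": truth.case_proteins,
        "defects": truth.defects[truth.defects != ""].to_dict(),
        "config": dataclasses.asdict(truth.config),
    }
    (outdir / "truth.json").write_text(json.dumps(t))


def read_dataset(indir):
    """Load a dataset written by :func:`write_dataset` (truth not required)."""
    indir = Path(indir)
    samples = pd.read_csv(indir / "samples.csv").set_index("sample_id", drop=False)
    mfi = pd.read_csv(indir / "mfi.csv").set_index("sample_id")
    matrix = MFIMatrix(mfi, samples["plate_id"], samples["role"])
    antibodies = pd.read_csv(indir / "antibodies.csv").set_index(
        "antibody_id", drop=False)
    empty = pd.read_csv(indir / "empty_wells.csv").set_index("antibody_id")[
        "empty_mfi"]
    igg = pd.read_csv(indir / "igg.csv").set_index("sample_id")["igg_mfi"]
    return samples, matrix, antibodies, empty, igg
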