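"""Configuration-driven orchestration of the full analysis.

Stage order follows the study design: simulate (or load) -> within- and
between-plate normalization -> antibody QC -> covariate adjustment ->
archetypal clustering with knee-based k selection -> bootstrap stability
and pair concordance -> cluster characterization -> matched case-control
models. Every stage writes CSV/JSON artifacts into the run directory
and a manifest records versions, seeds, input hashes and per-stage
shapes. Stage seeds are derived from the master seed by stable hashing
so any stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjust import CovariateAdjuster
from .archetypes import fit_archetypes, predict_coefficients, select_k
from .characterize import (cluster_clinical_tests, differential_abundance,
                           shortlist, trait_association)
from .clogit import screen_proteins_clogit
from .containers import MFIMatrix
from .normalize import abs_pqn, ma_normalize
from .qc import apply_qc, compute_qc, replicate_pairs_from_samples
from .simulate import (SimulationConfig, read_dataset, simulate_dataset,
                       write_dataset)
from .stability import bootstrap_mji, pair_concordance

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "normalize", "qc", "adjust", "cluster",
              "stability", "characterize", "casecontrol")


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed."""
    return (master * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _strict(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Validated, round-trippable pipeline configuration."""

    outdir: str = "run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    input_dir: str | None = None  # load a dataset instead of simulating
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    normalize: dict = field(default_factory=lambda: {"n_similar": 50, "span": 0.3})
    qc: dict = field(default_factory=lambda: {"rho_rep": 0.7, "rho_igg": 0.5,
                                              "bg_sd": 3.0})
    adjust: dict = field(default_factory=lambda: {
        "covariates": ["bmi", "age", "entry_date"]})
    cluster: dict = field(default_factory=lambda: {
        "k_min": 2, "k_max": 10, "restarts": 5, "max_iter": 200,
        "tol": 1e-6, "k": None})
    stability: dict = field(default_factory=lambda: {
        "B": 150, "restarts": 2, "n_random_pairs": 100})
    characterize: dict = field(default_factory=lambda: {
        "target_cluster": "auto", "m": 25})
    casecontrol: dict = field(default_factory=lambda: {"models": [1, 2, 3]})

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        _strict(d, {f.name for f in dataclasses.fields(cls)}, "pipeline config")
        _strict(d.get("simulate", {}),
                {f.name for f in dataclasses.fields(SimulationConfig)},
                "simulate")
        _strict(d.get("normalize", {}), {"n_similar", "span"}, "normalize")
        _strict(d.get("qc", {}), {"rho_rep", "rho_igg", "bg_sd"}, "qc")
        _strict(d.get("adjust", {}), {"covariates"}, "adjust")
        _strict(d.get("cluster", {}),
                {"k_min", "k_max", "restarts", "max_iter", "tol", "k"}, "cluster")
        _strict(d.get("stability", {}), {"B", "restarts", "n_random_pairs"},
                "stability")
        _strict(d.get("characterize", {}), {"target_cluster", "m"}, "characterize")
        _strict(d.get("casecontrol", {}), {"models"}, "casecontrol")
        base = cls()
        for section in ("normalize", "qc", "adjust", "cluster", "stability",
                        "characterize", "casecontrol"):
            merged = dict(getattr(base, section))
            merged.update(d.get(section, {}))
            d[section] = merged
        bad = set(d.get("stages", ALL_STAGES)) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        if "stages" in d:
            d["stages"] = list(d["stages"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ALL_STAGES if s in set(config.stages)]
    manifest: dict = {
        "package": "plasmarch",
        "version": __version__,
        "versions": {m.__name__: m.__version__ for m in (np, pd)},
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in stages},
        "stages": {},
        "config": config.to_dict(),
    }
    state: dict = {}

    for stage in stages:
        t0 = time.time()
        logger.info("stage %s ...", stage)
        try:
            _STAGE_FUNCS[stage](config, state, out)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        entry = {"seconds": round(time.time() - t0, 3)}
        for key in ("matrix_adj", "matrix_qc", "matrix_norm", "matrix"):
            if key in state:
                entry["n_samples"], entry["n_antibodies"] = state[key].shape
                break
        manifest["stages"][stage] = entry
        logger.info("stage %s done in %.1fs", stage, entry["seconds"])

    if config.input_dir:
        manifest["input_hashes"] = {
            f.name: _sha256(f) for f in sorted(Path(config.input_dir).glob("*.csv"))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, state, out):
    if config.input_dir:
        samples, matrix, ab, empty, igg = read_dataset(config.input_dir)
        state.update(samples=samples, matrix=matrix, antibodies=ab,
                     empty=empty, igg=igg, truth=None)
        return
    sim_kwargs = dict(config.simulate)
    sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
    sim = SimulationConfig(**sim_kwargs)
    records, matrix, ab, empty, igg, truth = simulate_dataset(sim)
    write_dataset(out, records, matrix, ab, empty, igg, truth)
    from .simulate import records_to_frame
    state.update(samples=records_to_frame(records), matrix=matrix,
                 antibodies=ab, empty=empty, igg=igg, truth=truth)


def _stage_normalize(config, state, out):
    m = abs_pqn(state["matrix"], n_similar=int(config.normalize["n_similar"]))
    if m.plates.nunique() >= 2:
        m = ma_normalize(m, span=float(config.normalize["span"]))
    state["matrix_norm"] = m
    _write_matrix(m, out / "mfi_norm.csv")


def _stage_qc(config, state, out):
    samples = state["samples"]
    pairs = replicate_pairs_from_samples(samples)
    report = compute_qc(state["matrix_norm"], pairs, state["igg"],
                        state["empty"], thresholds=config.qc)
    state["qc_report"] = report
    # keep doubles and replicates for prediction; pools are dropped here,
    # replicates only at the clustering stage
    state["matrix_qc"] = apply_qc(state["matrix_norm"], report,
                                  state["antibodies"], drop_roles=("pool",))
    report.antibody.to_csv(out / "qc_report.csv")
    _write_matrix(state["matrix_qc"], out / "mfi_qc.csv")


def _stage_adjust(config, state, out):
    samples = state["samples"]
    m = state["matrix_qc"]
    covs = list(config.adjust["covariates"])
    cov_table = samples.loc[m.values.index, covs].astype(float)
    complete = cov_table.notna().all(axis=1)
    m = m.subset(samples=m.values.index[complete])
    cov_table = cov_table.loc[m.values.index]
    study_idx = m.values.index[(m.roles == "study").to_numpy()]
    adj = CovariateAdjuster(covariates=covs).fit(
        m.subset(samples=study_idx), covariates=cov_table)
    state["scan"] = adj.scan()
    state["matrix_adj"] = adj.transform(m, covariates=cov_table)
    state["scan"].pvalues.to_csv(out / "scan.csv")
    _write_matrix(state["matrix_adj"], out / "mfi_adj.csv")


def _stage_cluster(config, state, out):
    m = state["matrix_adj"]
    study_idx = m.values.index[(m.roles == "study").to_numpy()]
    X = np.log(m.values.loc[study_idx].to_numpy())
    cc = config.cluster
    seed = stage_seed(config.seed, "cluster")
    if cc.get("k"):
        k_opt = int(cc["k"])
        curve = []
        model = fit_archetypes(X, k_opt, max_iter=int(cc["max_iter"]),
                               tol=float(cc["tol"]),
                               restarts=int(cc["restarts"]), seed=seed)
    else:
        k_opt, curve = select_k(X, range(int(cc["k_min"]), int(cc["k_max"]) + 1),
                                max_iter=int(cc["max_iter"]), tol=float(cc["tol"]),
                                restarts=int(cc["restarts"]), seed=seed)
        model = next(mdl for k, _, mdl in curve if k == k_opt)
    state["model"] = model
    state["cluster_X_index"] = study_idx
    labels = pd.Series(np.argmax(model.alpha, axis=1) + 1, index=study_idx)
    # predict held-out doubles and replicates against the fixed archetypes
    other_idx = m.values.index.difference(study_idx, sort=False)
    if len(other_idx):
        alpha_new = predict_coefficients(model, np.log(m.values.loc[other_idx]))
        labels = pd.concat([labels, pd.Series(
            np.argmax(alpha_new, axis=1) + 1, index=other_idx)])
    state["labels"] = labels
    labels.rename("cluster").rename_axis("sample_id").to_csv(out / "clusters.csv")
    (out / "model.json").write_text(json.dumps({
        "k": model.k, "rss": model.rss, "seed": seed,
        "rss_curve": [[k, r] for k, r, _ in curve],
        "Z": model.Z.tolist(), "alpha": model.alpha.tolist(),
        "beta": model.beta.tolist()}))


def _stage_stability(config, state, out):
    m = state["matrix_adj"]
    X = np.log(m.values.loc[state["cluster_X_index"]].to_numpy())
    sc = config.stability
    res = bootstrap_mji(X, state["model"], B=int(sc["B"]),
                        seed=stage_seed(config.seed, "stability"),
                        restarts=int(sc["restarts"]))
    state["stability"] = res
    samples = state["samples"]
    labels = state["labels"]
    rep_pairs = [p for p in replicate_pairs_from_samples(samples)
                 if p[0] in labels.index and p[1] in labels.index]
    dbl = samples[samples["role"] == "double"]
    dbl_pairs = []
    for _, grp in dbl.groupby("subject_id"):
        ids = [i for i in grp.index if i in labels.index]
        if len(ids) == 2:
            dbl_pairs.append(tuple(ids))
    conc = None
    if rep_pairs and dbl_pairs:
        conc = pair_concordance(labels, rep_pairs, dbl_pairs,
                                n_random_pairs=int(sc["n_random_pairs"]),
                                seed=stage_seed(config.seed, "concordance"),
                                study_ids=list(state["cluster_X_index"]))
        state["concordance"] = conc
    (out / "stability.json").write_text(json.dumps({
        "mji_mean": res.mji_mean.tolist(), "mji_sd": res.mji_sd.tolist(),
        "B": res.B,
        "concordance": None if conc is None else {
            "rates": conc.counts["rate"].to_dict(),
            "pvalues": {f"{a}_vs_{b}": conc.pvalues.loc[a, b]
                        for a in conc.pvalues.index for b in conc.pvalues.columns
                        if a < b}}}))


def _stage_characterize(config, state, out):
    cc = config.characterize
    labels = state["labels"].loc[state["cluster_X_index"]]
    target = cc["target_cluster"]
    if target == "auto":
        if "stability" in state:
            target = int(np.argmax(state["stability"].mji_mean) + 1)
        else:
            target = int(labels.value_counts().idxmin())
    target = int(target)
    m_adj = state["matrix_adj"].subset(samples=labels.index)
    m_norm = state["matrix_qc"].subset(samples=labels.index,
                                       antibodies=m_adj.antibody_ids)
    diff = differential_abundance(m_adj, labels, target, raw=m_norm.values)
    sl = shortlist(diff, m=int(cc["m"]))
    samples = state["samples"].loc[labels.index]
    variables = ["age", "bmi", "dense_area", "smoking", "alcohol", "prs",
                 "menopausal", "mht_status", "statin_status", "parity"]
    clin = cluster_clinical_tests(samples, labels, variables,
                                  mc_seed=stage_seed(config.seed, "characterize"))
    assoc = trait_association(m_adj, sorted(sl["higher"] | sl["lower"]), samples)
    state.update(differential=diff, shortlist=sl, clinical=clin,
                 associations=assoc, target_cluster=target)
    diff.table.to_csv(out / "differential.csv")
    (out / "shortlist.json").write_text(json.dumps(
        {k: sorted(v) for k, v in sl.items()}))
    pd.DataFrame([{
        "variable": c.variable, "test": c.test, "scope": c.scope,
        "groups": "|".join(map(str, c.groups)), "p": c.p}
        for c in clin]).to_csv(out / "clinical_tests.csv", index=False)
    assoc.to_csv(out / "associations.csv")


def _stage_casecontrol(config, state, out):
    m = state.get("matrix_qc", state.get("matrix"))
    samples = state["samples"]
    screen = screen_proteins_clogit(m, samples,
                                    models=list(config.casecontrol["models"]))
    state["casecontrol"] = screen
    screen.to_csv(out / "clogit.csv", index=False)


def _write_matrix(m: MFIMatrix, path: Path) -> None:
    df = m.values.copy()
    df.insert(0, "sample_id", df.index)
    df.to_csv(path, index=False, float_format="%.17g")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "qc": _stage_qc,
    "adjust": _stage_adjust,
    "cluster": _stage_cluster,
    "stability": _stage_stability,
    "characterize": _stage_characterize,
    "casecontrol": _stage_casecontrol,
}
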