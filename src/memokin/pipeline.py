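"""End-to-end orchestration of the analysis.

Stages, in dependency order:

1. ``data``        - load or synthesise the three observation tables.
2. ``replacement`` - fit donor-fraction timecourses per subset; derive
                     informative influx priors.
3. ``labelling``   - fit each configured topology to each stratified
                     BrdU/Ki67 timecourse, with the influx priors.
4. ``compare``     - ELPD/LOO ranking per stratum.
5. ``derive``      - net loss rates, clonal half-lives and
                     size-weighted mean lifespans from the posteriors.
6. ``predict``     - reporter-dilution and Ki67-transfer predictions.

Every stage reads its inputs from, and writes its outputs to, the run
directory, so a run is resumable: a manifest records the config
digest, seeds and outputs, and re-running with an unchanged config
skips completed stages (reloading their outputs from disk) rather
than recomputing them.  All stochastic stages derive their seeds
deterministically from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._mcmc import SamplerSettings
from .chimerism import InfluxPrior, fit_replacement, influx_prior_from_replacement
from .datamodel import Cohort, ExperimentDesign, Lineage, Subset
from . import io as mio
from .derived import summarize_draws
from .inference import PriorSpec, compare_pointwise, fit_labelling_model
from .models import KineticParameters, ModelTopology, close_parameters
from .predictions import (
    fit_source_dilution_curve,
    predict_label_dilution,
    predict_transfer_ki67,
)
from .synthetic import (
    generate_chimerism_dataset,
    generate_dilution_dataset,
    generate_labelling_dataset,
    default_ground_truth,
)

logger = logging.getLogger("memokin")

ALL_STRATA = [
    (c, s, l)
    for c in (Cohort.YOUNG, Cohort.OLD)
    for s in (Subset.TCM, Subset.TEM)
    for l in (Lineage.HOST, Lineage.DONOR)
]

#: Effector:central memory abundance ratio used for population averages.
DEFAULT_EM_CM_RATIO = 7.5

_STAGES = ["data", "replacement", "labelling", "compare", "derive", "predict"]


def default_config(outdir: str = "runs/demo", seed: int = 1) -> dict:
    return {
        "seed": seed,
        "outdir": outdir,
        "data": "synthetic",
        "truth_topology": "branched",
        "topologies": ["branched", "linear", "burst", "temporal"],
        "strata": "all",
        "design": {},
        "sampler": {"n_walkers": 32, "n_steps": 500, "n_burn": 300, "thin": 4},
        "replacement_sampler": {"n_walkers": 16, "n_steps": 500, "n_burn": 400},
        "em_cm_ratio": DEFAULT_EM_CM_RATIO,
        "predictions": {
            "dilution_times": [0, 10, 20, 40, 60, 90, 120],
            "n_draws": 200,
        },
        "chimerism_times": [float(t) for t in np.linspace(45, 600, 14)],
        "chimerism_mice_per_time": 4,
    }


def _digest(config: dict) -> str:
    # the output location does not alter what is computed
    cfg = {k: v for k, v in config.items() if k != "outdir"}
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _stage_seed(base: int, stage: str, extra: str = "") -> int:
    h = hashlib.sha256(f"{stage}:{extra}".encode()).digest()
    return (base * 1000003 + int.from_bytes(h[:4], "big")) % (2**31 - 1)


def _stratum_id(key) -> str:
    c, s, l = key
    return f"{c.value}_{s.value}_{l.value}"


def _parse_stratum_id(sid: str):
    c, s, l = sid.split("_")
    return (Cohort(c), Subset(s), Lineage(l))


@dataclass
class FitRecord:
    """Portable summary of one labelling fit (reloadable from disk)."""

    stratum: tuple
    topology: ModelTopology
    draws: pd.DataFrame  # natural-scale posterior draws
    elpd: float
    elpd_se: float
    loo_pointwise: np.ndarray


@dataclass
class RunManifest:
    """Record of one pipeline run: config digest, seeds, per-stage outputs."""

    config_digest: str
    seed: int
    outdir: str
    stages: dict = field(default_factory=dict)  # name -> {status, outputs, seconds}

    def to_dict(self) -> dict:
        return {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "outdir": self.outdir,
            "stages": self.stages,
        }

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        d = json.loads(path.read_text())
        return cls(
            config_digest=d["config_digest"], seed=d["seed"],
            outdir=d["outdir"], stages=d["stages"],
        )

    def stage_complete(self, name: str) -> bool:
        st = self.stages.get(name)
        if not st or st.get("status") != "complete":
            return False
        return all(Path(p).exists() for p in st.get("outputs", []))

    @property
    def all_outputs(self) -> list:
        return [p for st in self.stages.values() for p in st.get("outputs", [])]


def _parse_strata(config: dict) -> list:
    if config.get("strata", "all") == "all":
        return list(ALL_STRATA)
    return [(Cohort(c), Subset(s), Lineage(l)) for c, s, l in config["strata"]]


def run_full_analysis(config: dict) -> RunManifest:
    """Execute all stages; a stage failure halts downstream stages.

    Returns the manifest (also written to ``<outdir>/manifest.json``).
    Re-running with the same config and intact outputs skips completed
    stages.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    digest = _digest(config)
    manifest_path = outdir / "manifest.json"
    manifest = RunManifest(config_digest=digest, seed=config["seed"], outdir=str(outdir))
    if manifest_path.exists():
        prev = RunManifest.load(manifest_path)
        if prev.config_digest == digest:
            manifest = prev

    state: dict = {}
    runners = {
        "data": (_stage_data, _load_data),
        "replacement": (_stage_replacement, _load_replacement),
        "labelling": (_stage_labelling, _load_labelling),
        "compare": (_stage_compare, None),
        "derive": (_stage_derive, None),
        "predict": (_stage_predict, None),
    }
    for name in _STAGES:
        fn, loader = runners[name]
        if manifest.stage_complete(name):
            if loader is not None:
                loader(config, outdir, state)
            logger.info("stage %s: complete, skipping", name)
            continue
        t0 = time.perf_counter()
        logger.info("stage %s: starting", name)
        try:
            outputs = fn(config, outdir, state)
        except Exception:
            manifest.stages[name] = {"status": "failed", "outputs": []}
            manifest.save(manifest_path)
            raise
        manifest.stages[name] = {
            "status": "complete",
            "outputs": [str(p) for p in outputs],
            "seconds": round(time.perf_counter() - t0, 2),
        }
        manifest.save(manifest_path)
        logger.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
    return manifest


# ---------------------------------------------------------------------------
# stage: data
# ---------------------------------------------------------------------------


def _stage_data(config: dict, outdir: Path, state: dict) -> list:
    design = ExperimentDesign(**config.get("design", {}))
    state["design"] = design
    seed = config["seed"]
    if config.get("data", "synthetic") == "synthetic":
        topo = ModelTopology(config.get("truth_topology", "branched"))
        truth = default_ground_truth(topo, seed=seed)
        strata = _parse_strata(config)
        truth.params = {k: v for k, v in truth.params.items() if k in strata}
        lab = generate_labelling_dataset(
            truth, design, seed=_stage_seed(seed, "data", "labelling")
        )
        chi = generate_chimerism_dataset(
            truth,
            times=config.get("chimerism_times", default_config()["chimerism_times"]),
            mice_per_time=config.get("chimerism_mice_per_time", 4),
            seed=_stage_seed(seed, "data", "chimerism"),
        )
        dil = generate_dilution_dataset(
            (0.85, 0.25, 0.02),
            times=np.linspace(0, 130, 14),
            seed=_stage_seed(seed, "data", "dilution"),
        )
        mio.save_config(
            {
                "topology": truth.topology.value,
                "seed": truth.seed,
                "strata": {
                    _stratum_id(k): {
                        fld: float(getattr(v, fld))
                        for fld in (
                            "epsilon", "beta", "alpha_fast", "alpha_slow",
                            "delta_fast", "delta_slow", "f", "N_fast", "N_slow",
                            "phi_fast_fraction", "gamma", "activation", "reversion",
                        )
                    }
                    for k, v in truth.params.items()
                },
            },
            outdir / "ground_truth.yaml",
        )
    else:
        paths = config["data"]
        lab = mio.read_labelling_table(paths["labelling"])
        chi = mio.read_chimerism_table(paths["chimerism"])
        dil = (
            mio.read_dilution_table(paths["dilution"]) if "dilution" in paths else []
        )
    mio.write_labelling_table(lab, outdir / "labelling.csv")
    mio.write_chimerism_table(chi, outdir / "chimerism.csv")
    mio.write_dilution_table(dil, outdir / "dilution.csv")
    state.update(labelling=lab, chimerism=chi, dilution=dil)
    out = [outdir / "labelling.csv", outdir / "chimerism.csv", outdir / "dilution.csv"]
    if (outdir / "ground_truth.yaml").exists():
        out.append(outdir / "ground_truth.yaml")
    return out


def _load_data(config: dict, outdir: Path, state: dict) -> None:
    state["design"] = ExperimentDesign(**config.get("design", {}))
    state["labelling"] = mio.read_labelling_table(outdir / "labelling.csv")
    state["chimerism"] = mio.read_chimerism_table(outdir / "chimerism.csv")
    state["dilution"] = mio.read_dilution_table(outdir / "dilution.csv")


# ---------------------------------------------------------------------------
# stage: replacement
# ---------------------------------------------------------------------------


def _stage_replacement(config: dict, outdir: Path, state: dict) -> list:
    seed = config["seed"]
    settings = SamplerSettings(**config.get("replacement_sampler", {}))
    groups = mio.group_by_subset(state["chimerism"])
    priors, outputs, rows = {}, [], []
    for subset in (Subset.TCM, Subset.TEM):
        if subset not in groups:
            continue
        fit = fit_replacement(
            groups[subset], model="homogeneous", settings=settings,
            seed=_stage_seed(seed, "replacement", subset.value),
        )
        prior = influx_prior_from_replacement(fit.rate_draws, fit.source_draws)
        priors[subset] = prior
        p = outdir / f"replacement_draws_{subset.value}.csv"
        pd.DataFrame(
            {"rate": fit.rate_draws, "source_chimerism": fit.source_draws}
        ).to_csv(p, index=False)
        outputs.append(p)
        med = fit.median_parameters()
        rows.append(
            {
                "subset": subset.value,
                "rate_median": med.rate,
                "plateau_median": med.source_chimerism,
                "converged": fit.converged,
            }
        )
    mio.save_config(
        {s.value: pr.to_dict() for s, pr in priors.items()},
        outdir / "influx_priors.yaml",
    )
    pd.DataFrame(rows).to_csv(outdir / "replacement_summary.csv", index=False)
    state["influx_priors"] = priors
    return outputs + [outdir / "influx_priors.yaml", outdir / "replacement_summary.csv"]


def _load_replacement(config: dict, outdir: Path, state: dict) -> None:
    raw = mio.load_config(outdir / "influx_priors.yaml")
    state["influx_priors"] = {
        Subset(k): InfluxPrior.from_dict(v) for k, v in raw.items()
    }


# ---------------------------------------------------------------------------
# stage: labelling
# ---------------------------------------------------------------------------


def _group_labelling(obs) -> dict:
    groups: dict = {}
    for o in obs:
        groups.setdefault((o.cohort, o.subset, o.lineage), []).append(o)
    return groups


def _stage_labelling(config: dict, outdir: Path, state: dict) -> list:
    seed = config["seed"]
    design = state["design"]
    settings = SamplerSettings(**config.get("sampler", {}))
    topologies = [ModelTopology(t) for t in config.get("topologies", ["branched"])]
    groups = _group_labelling(state["labelling"])
    priors = state.get("influx_priors", {})
    records, outputs, diag_rows = [], [], []
    fit_dir = outdir / "fits"
    fit_dir.mkdir(exist_ok=True)
    for key in sorted(groups, key=_stratum_id):
        spec = PriorSpec(influx_prior=priors.get(key[1]))
        for topo in topologies:
            fit = fit_labelling_model(
                groups[key], topo, priors=spec, settings=settings,
                seed=_stage_seed(seed, "labelling", f"{_stratum_id(key)}:{topo.value}"),
                design=design,
            )
            nat = fit.posterior_params()
            base = f"{_stratum_id(key)}_{topo.value}"
            p1 = fit_dir / f"{base}.csv"
            nat.to_csv(p1, index=False)
            p2 = fit_dir / f"{base}_loo.csv"
            pd.DataFrame({"loo_i": fit.loo_pointwise}).to_csv(p2, index=False)
            outputs += [p1, p2]
            records.append(
                FitRecord(
                    stratum=key, topology=topo, draws=nat,
                    elpd=fit.elpd, elpd_se=fit.elpd_se,
                    loo_pointwise=fit.loo_pointwise,
                )
            )
            diag_rows.append(
                {
                    "stratum": _stratum_id(key),
                    "topology": topo.value,
                    "elpd": fit.elpd,
                    "elpd_se": fit.elpd_se,
                    "rhat_max": max(fit.sample.rhat.values()),
                    "ess_min": min(fit.sample.ess.values()),
                    "converged": fit.converged,
                    "seed": fit.seed,
                }
            )
    pd.DataFrame(diag_rows).to_csv(outdir / "fit_diagnostics.csv", index=False)
    state["fit_records"] = records
    return outputs + [outdir / "fit_diagnostics.csv"]


def _load_labelling(config: dict, outdir: Path, state: dict) -> None:
    diag = pd.read_csv(outdir / "fit_diagnostics.csv")
    fit_dir = outdir / "fits"
    records = []
    for _, row in diag.iterrows():
        base = f"{row.stratum}_{row.topology}"
        records.append(
            FitRecord(
                stratum=_parse_stratum_id(row.stratum),
                topology=ModelTopology(row.topology),
                draws=pd.read_csv(fit_dir / f"{base}.csv"),
                elpd=float(row.elpd),
                elpd_se=float(row.elpd_se),
                loo_pointwise=pd.read_csv(fit_dir / f"{base}_loo.csv")["loo_i"].to_numpy(),
            )
        )
    state["fit_records"] = records


# ---------------------------------------------------------------------------
# stages: compare / derive / predict
# ---------------------------------------------------------------------------


def _stage_compare(config: dict, outdir: Path, state: dict) -> list:
    records = state["fit_records"]
    strata = sorted({r.stratum for r in records}, key=_stratum_id)
    tables = []
    for key in strata:
        group = [r for r in records if r.stratum == key]
        if len(group) < 2:
            continue
        cmp = compare_pointwise(
            [r.topology.value for r in group],
            [r.loo_pointwise for r in group],
            elpd_se=[r.elpd_se for r in group],
        )
        tab = cmp.table.copy()
        tab.insert(0, "stratum", _stratum_id(key))
        tables.append(tab)
    out = outdir / "model_comparison.csv"
    (pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()).to_csv(
        out, index=False
    )
    return [out]


def _reference_topology(config: dict) -> ModelTopology:
    return ModelTopology(config.get("topologies", ["branched"])[0])


def _stage_derive(config: dict, outdir: Path, state: dict) -> list:
    records = state["fit_records"]
    topo = _reference_topology(config)
    ratio = config.get("em_cm_ratio", DEFAULT_EM_CM_RATIO)
    rows, lifespans = [], {}
    for r in records:
        if r.topology is not topo:
            continue
        nat = r.draws
        derived = pd.DataFrame(
            {
                "lambda_fast": nat["lambda_fast"],
                "lambda_slow": nat["lambda_slow"],
                "half_life_fast": np.where(
                    nat["lambda_fast"] > 0, np.log(2) / nat["lambda_fast"], np.inf
                ),
                "half_life_slow": np.where(
                    nat["lambda_slow"] > 0, np.log(2) / nat["lambda_slow"], np.inf
                ),
                "mean_lifespan": 1.0
                / (
                    nat["n_fast_frac"] * nat["delta_fast"]
                    + (1 - nat["n_fast_frac"]) * nat["delta_slow"]
                ),
            }
        )
        summ = summarize_draws(derived)
        summ.insert(0, "stratum", _stratum_id(r.stratum))
        rows.append(summ)
        lifespans[r.stratum] = derived["mean_lifespan"].to_numpy()
    out = outdir / "derived_quantities.csv"
    pd.concat(rows, ignore_index=True).to_csv(out, index=False)

    # population averages across subsets at the EM:CM abundance ratio,
    # combining loss rates (not lifespans): lifespan = 1 / E_w[delta]
    coh_rows = []
    for cohort in (Cohort.YOUNG, Cohort.OLD):
        per_subset = {}
        for subset in (Subset.TCM, Subset.TEM):
            arrs = [v for k, v in lifespans.items() if k[0] == cohort and k[1] == subset]
            if arrs:
                n = min(map(len, arrs))
                per_subset[subset] = np.mean([a[:n] for a in arrs], axis=0)
        if len(per_subset) == 2:
            n = min(len(per_subset[Subset.TCM]), len(per_subset[Subset.TEM]))
            mean_delta = (
                1.0 / per_subset[Subset.TCM][:n] + ratio / per_subset[Subset.TEM][:n]
            ) / (1.0 + ratio)
            inv = 1.0 / mean_delta
            coh_rows.append(
                {
                    "cohort": cohort.value,
                    "lifespan_TCM_median": float(np.median(per_subset[Subset.TCM])),
                    "lifespan_TEM_median": float(np.median(per_subset[Subset.TEM])),
                    "lifespan_all_median": float(np.median(inv)),
                    "lifespan_all_q2.5": float(np.percentile(inv, 2.5)),
                    "lifespan_all_q97.5": float(np.percentile(inv, 97.5)),
                }
            )
    out2 = outdir / "cohort_lifespans.csv"
    pd.DataFrame(coh_rows).to_csv(out2, index=False)
    return [out, out2]


def _params_from_natural_row(row, topo: ModelTopology) -> KineticParameters:
    nf = float(row["n_fast_frac"])
    kw = dict(
        epsilon=float(row["epsilon"]), beta=float(row["beta"]),
        alpha_fast=float(row["alpha_fast"]), alpha_slow=float(row["alpha_slow"]),
        f=float(row["f"]), N_fast=nf, N_slow=1.0 - nf,
    )
    if topo is ModelTopology.BRANCHED:
        kw["phi_fast_fraction"] = float(row["phi_fast_fraction"])
    elif topo is ModelTopology.LINEAR:
        kw["gamma"] = float(row["gamma"])
    elif topo is ModelTopology.BURST:
        kw["activation"] = float(row["activation"])
        kw["reversion"] = float(row["reversion"])
    return close_parameters(KineticParameters(**kw), topo)


def _stage_predict(config: dict, outdir: Path, state: dict) -> list:
    records = state["fit_records"]
    topo = _reference_topology(config)
    seed = config["seed"]
    pcfg = config.get("predictions", {})
    times = np.asarray(pcfg.get("dilution_times", [0, 30, 60, 90, 120]), float)
    n_draws = int(pcfg.get("n_draws", 200))
    outputs = []

    src = None
    naive = [o for o in state.get("dilution", []) if o.subset == Subset.NAIVE_CD4]
    if len(naive) >= 5:
        src = fit_source_dilution_curve(naive)

    def stratum_record(subset) -> Optional[FitRecord]:
        for r in records:
            if r.topology is topo and r.stratum[1] == subset and r.stratum[2] == Lineage.DONOR:
                return r
        return None

    def draw_params(record, n, rng_seed):
        nat = record.draws
        idx = np.random.default_rng(rng_seed).choice(
            len(nat), size=min(n, len(nat)), replace=False
        )
        return [_params_from_natural_row(nat.iloc[i], topo) for i in idx]

    tcm_rec, tem_rec = stratum_record(Subset.TCM), stratum_record(Subset.TEM)
    if src is not None and tcm_rec is not None:
        s0 = _stage_seed(seed, "predict", "dilution")
        pred_tcm = predict_label_dilution(
            draw_params(tcm_rec, n_draws, s0), topo, src, times, seed=s0
        )
        p = outdir / "dilution_prediction_TCM.csv"
        pd.DataFrame(
            {"time": times, "median": pred_tcm.median, "lo": pred_tcm.lo, "hi": pred_tcm.hi}
        ).to_csv(p, index=False)
        outputs.append(p)
        if tem_rec is not None:
            draws2 = draw_params(tem_rec, len(pred_tcm.draws_total), s0 + 1)
            pred_tem = predict_label_dilution(
                draws2, topo, pred_tcm.source_for_chaining("total"), times, seed=s0 + 1
            )
            p2 = outdir / "dilution_prediction_TEM.csv"
            pd.DataFrame(
                {"time": times, "median": pred_tem.median, "lo": pred_tem.lo, "hi": pred_tem.hi}
            ).to_csv(p2, index=False)
            outputs.append(p2)

    if tem_rec is not None:
        params = _params_from_natural_row(tem_rec.draws.median(), topo)
        rows = []
        for cohort_name in ("yfp_pos", "yfp_neg", "bulk"):
            for influx_on in (False, True):
                tp = predict_transfer_ki67(
                    params, topo, cohort_name, influx_on=influx_on,
                    times=np.linspace(0, 7, 8),
                )
                rows += [
                    {"cohort": cohort_name, "influx_on": influx_on,
                     "time": float(t), "frac_ki67hi": float(k)}
                    for t, k in zip(tp.times, tp.ki67hi_fraction)
                ]
        p3 = outdir / "transfer_ki67_prediction.csv"
        pd.DataFrame(rows).to_csv(p3, index=False)
        outputs.append(p3)
    return outputs
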