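"""End-to-end pipeline: simulate -> score -> impute -> derive -> validate.

Every stage reads and writes plain CSV/JSON in a run directory; a
manifest records the configuration, seeds, software versions and SHA-256
hashes of all outputs, so a rerun with the same configuration reproduces
identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohorts, derivation, imputation, mixedlm
from . import radiographic, scores, ultrasound

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

STAGES = ("simulate", "score", "impute", "derive", "validate")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "das2c_run"
    cohort_scale: float = 1.0      # shrink cohort sizes for quick runs
    k_folds: int = 20
    m_imputations: int = 20
    crp_substitute: float | None = None  # None: take it from the impute stage
    stages: tuple[str, ...] = STAGES
    truth: cohorts.TruthRecord = field(default_factory=cohorts.TruthRecord)
    radiograph_truth: cohorts.RadiographTruth = field(
        default_factory=cohorts.RadiographTruth)

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.m_imputations < 2:
            raise ValueError("m_imputations must be >= 2")
        if not 0 < self.cohort_scale <= 2:
            raise ValueError("cohort_scale must be in (0, 2]")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        truth = cohorts.TruthRecord(**raw.pop("truth", {}))
        rtruth = cohorts.RadiographTruth(**raw.pop("radiograph_truth", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(truth=truth, radiograph_truth=rtruth, **raw)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    truth = dataclasses.replace(cfg.truth, seed=cfg.seed)
    rtruth = dataclasses.replace(cfg.radiograph_truth, seed=cfg.seed + 1)
    specs = cohorts.default_development_specs(cfg.cohort_scale)
    dev = cohorts.generate_development_cohorts(specs, truth)
    for name, tables in dev.items():
        _write_csv(tables["visits"], outdir / f"visits_{name}.csv")
        _write_csv(tables["ultrasound"], outdir / f"ultrasound_{name}.csv")
    vspec = cohorts.default_validation_spec(cfg.cohort_scale)
    radio = cohorts.generate_validation_cohort(vspec, rtruth)
    _write_csv(radio, outdir / "radiographs.csv")
    (outdir / "truth.json").write_text(json.dumps({
        "development": dataclasses.asdict(truth),
        "validation": dataclasses.asdict(rtruth),
        "methods": {s.name: s.gspd_method for s in specs},
    }, indent=2, sort_keys=True))


def stage_score(cfg: RunConfig, outdir: Path) -> None:
    methods = json.loads((outdir / "truth.json").read_text())["methods"]
    substitute = _current_substitute(cfg, outdir)
    for name, method in methods.items():
        ultra = pd.read_csv(outdir / f"ultrasound_{name}.csv")
        scale_max = 4 if method == "sum10" else 3
        gspd = ultrasound.gspd_from_table(ultra, method, scale_max)
        _write_csv(gspd, outdir / f"gspd_{name}.csv")
        visits = pd.read_csv(outdir / f"visits_{name}.csv")
        scored = scores.add_score_columns(visits, crp_substitute=substitute)
        _write_csv(scored, outdir / f"scored_{name}.csv")


def _current_substitute(cfg: RunConfig, outdir: Path) -> float:
    if cfg.crp_substitute is not None:
        return cfg.crp_substitute
    log_path = outdir / "imputation_log.json"
    if log_path.exists():
        return json.loads(log_path.read_text())["crp_substitute"]
    return scores.DEFAULT_CRP_SUBSTITUTE


def stage_impute(cfg: RunConfig, outdir: Path) -> None:
    methods = json.loads((outdir / "truth.json").read_text())["methods"]
    largest = max(methods, key=lambda n: len(pd.read_csv(
        outdir / f"visits_{n}.csv")))
    visits = pd.read_csv(outdir / f"visits_{largest}.csv")
    mask = visits["crp_censored"].fillna(False).astype(bool) & visits["crp"].notna()
    observed = visits["crp"].notna()
    series = imputation.CensoredSeries(
        visits.loc[observed, "crp"].to_numpy(),
        mask[observed].to_numpy(),
        threshold=5.0,
    )
    ros = imputation.ros_impute(series)
    substitute = imputation.select_single_substitute(ros.imputed)

    for name in methods:
        visits_c = pd.read_csv(outdir / f"visits_{name}.csv")
        completed = imputation.mice_pmm(
            visits_c, m=cfg.m_imputations, seed=cfg.seed + 10)
        for i, ds in enumerate(completed.datasets, start=1):
            _write_csv(ds, outdir / f"completed_{name}_{i}.csv")
    (outdir / "imputation_log.json").write_text(json.dumps({
        "crp_substitute": substitute,
        "ros_median_imputed": float(np.median(ros.imputed)),
        "ros_n_imputed": int(ros.imputed.size),
        "m": cfg.m_imputations,
        "n_cycles": 10,
        "k_pmm": 5,
        "seed": cfg.seed + 10,
        "largest_cohort": largest,
    }, indent=2, sort_keys=True))


_CANDIDATE_SPECS = {
    "2C_CRP": ("ln_crp1", "sqrt_sjc28"),
    "4C_CRP": ("ln_crp1", "sqrt_sjc28", "sqrt_tjc28", "ghvas"),
    "2C_ESR": ("ln_esr", "sqrt_sjc28"),
    "4C_ESR": ("ln_esr", "sqrt_sjc28", "sqrt_tjc28", "ghvas"),
}
_SCORE_SPECS = ("das28_2c_crp", "das28_3c_crp", "das28_4c_crp",
                "das28_4c_esr", "partial_sdai", "partial_cdai")


def stage_derive(cfg: RunConfig, outdir: Path) -> None:
    methods = json.loads((outdir / "truth.json").read_text())["methods"]
    substitute = _current_substitute(cfg, outdir)
    cv_rows = []
    ratios = {"CRP": [], "ESR": []}
    for name in methods:
        raw = pd.read_csv(outdir / f"visits_{name}.csv")
        datasets = []
        for i in range(1, cfg.m_imputations + 1):
            ds = pd.read_csv(outdir / f"completed_{name}_{i}.csv")
            ds["crp"] = scores.resolve_censored_crp(
                ds["crp"], ds["crp_censored"].astype(bool), substitute)
            ds = mixedlm.add_transformed_components(ds)
            ds = scores.add_score_columns(ds, _SCORE_SPECS, substitute)
            datasets.append(ds)

        # component ratios from Rubin-pooled 2C coefficients
        for ap, term in (("CRP", "ln_crp1"), ("ESR", "ln_esr")):
            spec = mixedlm.ModelSpec(("sqrt_sjc28", term))
            fits = [mixedlm.fit_lmm(ds, spec) for ds in datasets]
            pooled = imputation.rubin_pool(
                np.array([f.beta.to_numpy() for f in fits]),
                np.array([f.beta_se.to_numpy() ** 2 for f in fits]))
            beta = pd.Series(pooled.estimate, index=fits[0].beta.index)
            n_weight = int(raw[ap.lower()].notna().sum())
            try:
                ratios[ap].append(derivation.ratio_from_coefficients(
                    name, float(beta["sqrt_sjc28"]), float(beta[term]), n_weight))
            except ValueError as exc:
                # a non-positive acute-phase coefficient cannot enter the
                # score; drop the cohort from this acute-phase combination
                logger.warning("%s %s ratio skipped: %s", name, ap, exc)

        folds = mixedlm.assign_folds(
            datasets[0]["patient_id"].to_numpy(), cfg.k_folds, cfg.seed + 20)
        for label, fixed in _CANDIDATE_SPECS.items():
            rep = mixedlm.kfold_cv(datasets, mixedlm.ModelSpec(fixed),
                                   k=cfg.k_folds, folds=folds)
            cv_rows.append((name, label, rep.r2, rep.test_loglik))
        for score in _SCORE_SPECS:
            rep = mixedlm.kfold_cv(datasets, mixedlm.ModelSpec((score,)),
                                   k=cfg.k_folds, folds=folds)
            cv_rows.append((name, score, rep.r2, rep.test_loglik))

    equations = {ap: derivation.derive_equation(r, ap)
                 for ap, r in ratios.items() if r}
    (outdir / "score_equation.json").write_text(json.dumps({
        ap: json.loads(eq.to_json()) for ap, eq in equations.items()
    } | {"seed": cfg.seed, "version": __version__}, indent=2, sort_keys=True))

    cv = pd.DataFrame(cv_rows, columns=["cohort", "model", "r2", "test_loglik"])
    cv["delta_from_best"] = cv.groupby("cohort")["test_loglik"].transform(
        lambda s: s - s.max())
    _write_csv(cv, outdir / "cv_report.csv")


def stage_validate(cfg: RunConfig, outdir: Path) -> None:
    substitute = _current_substitute(cfg, outdir)
    radio = pd.read_csv(outdir / "radiographs.csv")
    eq_path = outdir / "score_equation.json"
    if eq_path.exists():
        weight = json.loads(eq_path.read_text()).get(
            "CRP", {}).get("weight_ap", 0.6)
    else:
        weight = 0.6
    radio["das28_2c_crp"] = scores.das28_2c_crp(
        radio["sjc28"], radio["crp"], weight)
    radio["das28_3c_crp"] = scores.das28_3c_crp(
        radio["tjc28"], radio["sjc28"], radio["crp"])
    report = radiographic.validation_report(
        radio,
        score_columns={"2C-DAS28CRP": "das28_2c_crp",
                       "3C-DAS28CRP": "das28_3c_crp"},
    )
    _write_csv(report, outdir / "validation_report.csv")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "score": stage_score,
    "impute": stage_impute,
    "derive": stage_derive,
    "validate": stage_validate,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the configured stages in order and write a manifest.

    Raises RuntimeError naming the failing stage on any error.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "config": {
            **{k: v for k, v in dataclasses.asdict(cfg).items()
               if k not in ("truth", "radiograph_truth")},
            "truth": dataclasses.asdict(cfg.truth),
            "radiograph_truth": dataclasses.asdict(cfg.radiograph_truth),
        },
        "versions": {
            "das2c": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {p.name: _sha256(p)
                    for p in sorted(outdir.glob("*.csv"))
                    + sorted(outdir.glob("*.json"))
                    if p.name != "manifest.json"},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=list))
    return outdir
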