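"""End-to-end orchestration: simulate/load -> preprocess -> pairwise models
-> validation -> significance table -> multivariate ROC -> ratio ROC.

Every stage writes plain-text artifacts (CSV/TSV/JSON) plus a run manifest
recording the seed, settings and library versions, so a run is fully
reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarker import multivariate_roc, ratio_feature, roc_curve
from .chemometrics import cv_anova, fit_oplsda, fit_pca, permutation_test
from .errors import ConfigError
from .preprocess import BinnedMatrix, preprocess_cohort
from .reference import COMPARISONS, load_reference
from .significance import COMPARISON_GROUPS, differential_table, quantify_metabolites
from .synthdata import CohortConfig, read_cohort, simulate_cohort


@dataclass
class PreprocessConfig:
    lo: float = 0.0
    hi: float = 9.0
    width: float = 0.001
    water_lo: float = 4.6
    water_hi: float = 5.1


@dataclass
class ModelConfig:
    scaling: str = "uv"
    n_orth: int = 1
    cv_folds: int = 7
    n_perm: int = 200


@dataclass
class SignificanceConfig:
    alphas: list = field(default_factory=lambda: [0.05, 0.01])
    half_width: float = 0.01


@dataclass
class BiomarkerConfig:
    n_features: int = 5
    n_splits: int = 100
    n_trees: int = 500
    ratio_pairs: list = field(
        default_factory=lambda: [["Acetate", "Glycerol"], ["Lactate", "Citrate"]]
    )


@dataclass
class PipelineConfig:
    """Declarative configuration; defaults reproduce the study settings
    (0-9 ppm at 0.001 ppm bins, 4.6-5.1 ppm water exclusion, VIP > 1 with
    alpha in {0.05, 0.01}, five ROC features)."""

    seed: int = 0
    input_manifest: str | None = None  # load spectra instead of simulating
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    biomarker: BiomarkerConfig = field(default_factory=BiomarkerConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        try:
            for key, sub in (
                ("cohort", CohortConfig),
                ("preprocess", PreprocessConfig),
                ("model", ModelConfig),
                ("significance", SignificanceConfig),
                ("biomarker", BiomarkerConfig),
            ):
                if key in data and isinstance(data[key], dict):
                    data[key] = sub(**data[key])
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"invalid pipeline config: {exc}") from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError("pipeline config must be a mapping")
        return cls.from_dict(data)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


@dataclass
class ReportBundle:
    """In-memory handles to everything run_all computed."""

    matrix: BinnedMatrix
    models: dict
    validations: dict
    quant: pd.DataFrame
    significance: object
    multi_roc: dict
    ratio_roc: dict
    manifest: dict
    outdir: Path


def run_all(config: PipelineConfig, outdir: str | Path) -> ReportBundle:
    """Execute the full analysis and write all artifacts under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = load_reference()

    # --- cohort ---------------------------------------------------------
    if config.input_manifest:
        spectra = read_cohort(config.input_manifest)
    else:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        spectra = simulate_cohort(ref, cohort_cfg)

    # --- preprocessing --------------------------------------------------
    pp = config.preprocess
    matrix = preprocess_cohort(
        spectra, lo=pp.lo, hi=pp.hi, width=pp.width, water=(pp.water_lo, pp.water_hi)
    )
    matrix.write_csv(outdir / "binned_matrix.csv")
    _write_json(outdir / "preprocess_provenance.json", _jsonable(matrix.provenance))

    # --- overview PCA ---------------------------------------------------
    pca = fit_pca(matrix, n_components=3, scaling=config.model.scaling)
    pd.DataFrame(
        pca.scores, index=matrix.sample_ids, columns=["PC1", "PC2", "PC3"]
    ).to_csv(outdir / "pca_scores.csv")

    # --- pairwise OPLS-DA models with validation ------------------------
    mc = config.model
    models, validations = {}, {}
    for comp in COMPARISONS:
        case, base = COMPARISON_GROUPS[comp]
        sub = matrix.subset((case, base))
        model = fit_oplsda(
            sub, sub.groups, n_orth=mc.n_orth, scaling=mc.scaling, cv_k=mc.cv_folds
        )
        spec = {"kind": "oplsda", "n_orth": mc.n_orth, "scaling": mc.scaling}
        rpt = permutation_test(
            sub, sub.groups, n_perm=mc.n_perm, seed=config.seed + 1,
            modelspec=spec, k=mc.cv_folds,
        )
        rpt.cv_anova = cv_anova(sub, sub.groups, modelspec=spec, k=mc.cv_folds)
        models[comp], validations[comp] = model, rpt
        summary = model.summary() | {
            "rpt_intercepts": list(rpt.rpt_intercepts),
            "empirical_p": rpt.empirical_p,
            "cv_anova": rpt.cv_anova._asdict(),
        }
        _write_json(outdir / f"model_{comp}.json", _jsonable(summary))
        pd.DataFrame(
            {"tp1": model.scores[:, 0], "group": sub.groups}, index=sub.sample_ids
        ).to_csv(outdir / f"scores_{comp}.csv")

    # --- significance ---------------------------------------------------
    quant = quantify_metabolites(matrix, ref, half_width=config.significance.half_width)
    quant.to_csv(outdir / "metabolite_quant.csv")
    sig = differential_table(
        quant, models, matrix, ref,
        half_width=config.significance.half_width,
        alphas=tuple(config.significance.alphas),
    )
    sig.write_tsv(outdir / "significance_table.tsv")

    # --- multivariate ROC (each patient group vs control) ---------------
    bc = config.biomarker
    groups = np.asarray(matrix.groups)
    multi = {}
    for comp in ("polyp_vs_control", "crc_vs_control"):
        case, base = COMPARISON_GROUPS[comp]
        sel = np.isin(groups, (case, base))
        roc, ranking = multivariate_roc(
            quant.loc[sel], groups[sel],
            n_features=bc.n_features, n_splits=bc.n_splits,
            seed=config.seed + 2, n_trees=bc.n_trees,
        )
        multi[comp] = (roc, ranking)
        _write_json(
            outdir / f"multiroc_{comp}.json",
            {
                "roc": roc.summary(),
                "selected_frequency": ranking.frequency.round(6).to_dict(),
            },
        )

    # --- ratio biomarkers ----------------------------------------------
    ratio_reports = {}
    for num, den in bc.ratio_pairs:
        feature = ratio_feature(quant, num, den)
        per_comp = {}
        for comp in COMPARISONS:
            case, base = COMPARISON_GROUPS[comp]
            sel = np.isin(groups, (case, base))
            roc = roc_curve(feature[sel], groups[sel])
            per_comp[comp] = roc
        ratio_reports[feature.name] = per_comp
        _write_json(
            outdir / f"ratio_roc_{num}_{den}.json",
            {comp: roc.summary() for comp, roc in per_comp.items()},
        )

    # --- manifest -------------------------------------------------------
    import sklearn
    import scipy

    n_masked = int(matrix.excluded_mask.sum())
    manifest = {
        "serumnmr_version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_samples": matrix.n_samples,
        "n_bins": matrix.n_bins,
        "n_masked_bins": n_masked,
        "n_active_bins": matrix.n_bins - n_masked,
    }
    _write_json(outdir / "manifest.json", _jsonable(manifest))

    return ReportBundle(
        matrix=matrix,
        models=models,
        validations=validations,
        quant=quant,
        significance=sig,
        multi_roc=multi,
        ratio_roc=ratio_reports,
        manifest=manifest,
        outdir=outdir,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
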