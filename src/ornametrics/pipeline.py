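"""End-to-end orchestration: score -> normalize -> summarize -> test -> PGLS.

A run is fully specified by a :class:`RunConfig` (loadable from YAML).  Every
stage is a pure function of its persisted inputs, the config and the seed;
rerunning with the same config and seed reproduces every output table byte
for byte.  A JSON-lines run log records package versions, the seed and a
config hash, which is sufficient to re-execute the run exactly.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .complexity import complexity_score, normalize_dimorphism
from .morphometrics import (
    sex_difference_tests,
    size_time_correlations,
    summarize_panel,
)
from .outlines import read_outline_csv
from .phylo import PGLS, read_newick

__all__ = ["RunConfig", "run_full_analysis", "score_manifest"]


@dataclass(frozen=True)
class ModelConfig:
    """One PGLS regression: response, ordered predictors, lambda mode."""

    name: str
    response: str
    predictors: tuple[str, ...]
    lam: float | str = "ML"


@dataclass(frozen=True)
class RunConfig:
    """Inputs, parameters and outputs of one full analysis run."""

    out_dir: str
    panel_csv: str | None = None
    manifest_csv: str | None = None
    tree_file: str | None = None
    h_low: int = 8
    h_high: int = 1000
    models: tuple[ModelConfig, ...] = ()
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.h_low >= self.h_high:
            raise ValueError("h_low must be < h_high")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        models = tuple(
            ModelConfig(name=m["name"], response=m["response"],
                        predictors=tuple(m["predictors"]),
                        lam=m.get("lam", "ML"))
            for m in raw.pop("models", []))
        cfg = cls(models=models, **raw)
        for p in (cfg.panel_csv, cfg.manifest_csv, cfg.tree_file):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg

    def hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items() if k != "models"}
            | {"models": [m.__dict__ | {"predictors": list(m.predictors)}
                          for m in self.models]},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def score_manifest(manifest: pd.DataFrame, h_low: int = 8,
                   h_high: int = 1000) -> pd.DataFrame:
    """Score every outline listed in a manifest.

    The manifest has columns ``species, sex, trait, outline_csv``; the output
    adds congruent/non-congruent areas and the complexity value per row.
    """
    rows = []
    for rec in manifest.to_dict("records"):
        try:
            outline = read_outline_csv(rec["outline_csv"])
            score = complexity_score(outline, h_low=h_low, h_high=h_high)
        except Exception as exc:  # noqa: BLE001 - stage contract
            raise StageError("score", f"{rec.get('outline_csv')}: {exc}") from exc
        rows.append({
            "species": rec["species"], "sex": rec["sex"], "trait": rec["trait"],
            "source_id": rec["outline_csv"], "h_low": score.h_low,
            "h_high": score.h_high, "congruent_area": score.congruent_area,
            "noncongruent_area": score.noncongruent_area,
            "complexity": score.value,
        })
    return pd.DataFrame(rows)


def normalized_complexity_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Male/female normalized complexity per species for the paired traits.

    Claspers are male-only and are never normalized; they are passed through
    with the raw male score.
    """
    rows = []
    for (species, trait), grp in scores.groupby(["species", "trait"]):
        by_sex = grp.groupby("sex")["complexity"].mean()
        male = by_sex.get("male")
        if male is None:
            continue
        if trait == "clasper":
            rows.append({"species": species, "trait": trait,
                         "male_score": male, "female_score": float("nan"),
                         "normalized": float("nan"), "male_only": True})
            continue
        norm = normalize_dimorphism(male, by_sex.get("female"), species, trait)
        rows.append({"species": species, "trait": trait,
                     "male_score": norm.male_score,
                     "female_score": norm.female_score,
                     "normalized": norm.normalized, "male_only": False})
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and persist all tables under ``out_dir``.

    Returns the result bundle: a dict of DataFrames plus the run-log path.
    Any stage failure aborts with a :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_fh = log_path.open("w")

    def log(stage: str, **kv):
        log_fh.write(json.dumps({"stage": stage, **kv}, sort_keys=True,
                                default=str) + "\n")
        log_fh.flush()

    log("start", version=__version__, python=platform.python_version(),
        seed=config.seed, config_hash=config.hash())
    bundle: dict = {"log_path": log_path}
    try:
        if config.manifest_csv:
            manifest = pd.read_csv(config.manifest_csv)
            scores = score_manifest(manifest, config.h_low, config.h_high)
            scores.to_csv(out / "complexity_scores.csv", index=False)
            normalized = normalized_complexity_table(scores)
            normalized.to_csv(out / "complexity_normalized.csv", index=False)
            bundle["complexity_scores"] = scores
            bundle["complexity_normalized"] = normalized
            log("score", n_outlines=len(scores))

        if config.panel_csv is None:
            log("done", tables=sorted(k for k in bundle if k != "log_path"))
            return bundle

        records = pd.read_csv(config.panel_csv)
        try:
            summary = summarize_panel(records)
        except Exception as exc:  # noqa: BLE001
            raise StageError("summarize", str(exc)) from exc
        summary.means.to_csv(out / "species_sex_means.csv", index=False)
        species_means = summary.differences
        species_means.to_csv(out / "species_differences.csv")
        bundle["species_sex_means"] = summary.means
        bundle["species_differences"] = summary.differences
        log("summarize", n_species=summary.means["species"].nunique(),
            incomplete=list(summary.incomplete_species))

        ttests = sex_difference_tests(summary)
        ttests.to_csv(out / "sex_difference_ttests.csv", index=False)
        bundle["sex_difference_ttests"] = ttests
        log("ttests", n_tests=len(ttests))

        size_cols = [c for c in summary.means.columns if c.endswith("_area_mm2")]
        corr = size_time_correlations(
            summary, size_cols, ["larval_h", "pupal_h", "total_h"])
        corr.to_csv(out / "size_time_correlations.csv", index=False)
        bundle["size_time_correlations"] = corr
        log("correlations", n_pairs=len(corr))

        if config.tree_file and config.models:
            tree = read_newick(config.tree_file)
            coef_rows, anova_rows = [], []
            for m in config.models:
                cols = [m.response, *m.predictors]
                data = summary.differences.join(
                    summary.means.pivot(index="species", columns="sex")
                    .pipe(lambda d: d.set_axis(
                        [f"{q}_{s}" for q, s in d.columns], axis=1)))
                missing = [c for c in cols if c not in data.columns]
                if missing:
                    raise StageError("pgls", f"{m.name}: missing columns {missing}")
                rows_before = len(data)
                data = data.dropna(subset=cols)
                log("pgls_data", model=m.name,
                    dropped_for_missing=rows_before - len(data))
                try:
                    res = PGLS.from_dataframe(data, m.response,
                                              list(m.predictors), tree).fit(m.lam)
                except Exception as exc:  # noqa: BLE001
                    raise StageError("pgls", f"{m.name}: {exc}") from exc
                tab = res.to_frame().reset_index(names="term")
                tab.insert(0, "model", m.name)
                tab["lam"] = res.lam
                tab["llf"] = res.llf
                tab["n"] = res.nobs
                coef_rows.append(tab)
                an = res.anova().reset_index()
                an.insert(0, "model", m.name)
                anova_rows.append(an)
                log("pgls_fit", model=m.name, lam=res.lam, n=res.nobs)
            coefs = pd.concat(coef_rows, ignore_index=True)
            anova = pd.concat(anova_rows, ignore_index=True)
            coefs.to_csv(out / "pgls_coefficients.csv", index=False)
            anova.to_csv(out / "pgls_anova.csv", index=False)
            bundle["pgls_coefficients"] = coefs
            bundle["pgls_anova"] = anova

        log("done", tables=sorted(k for k in bundle if k != "log_path"))
        return bundle
    finally:
        log_fh.close()
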