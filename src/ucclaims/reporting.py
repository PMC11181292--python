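"""Cohort summary tables, percentage formatting, and the end-to-end run.

Percentages are formatted as the field tabulates them: one decimal,
half-up rounding (119/2669 -> 4.5).  Summaries are emitted overall and
stratified by onset group, mirroring the standard background/outcome
table layout of claims cohort reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bundle import ClaimsBundle
from .catalog import DrugCatalog, default_catalog, load_catalog
from .cohort import build_cohort
from .episodes import first_mtd
from .regression import (
    DegenerateFitError,
    chi_square_compare,
    fit_outcome_model,
    median_iqr,
)
from .simulate import GeneratorConfig, generate_claims
from .survival import extract_time_to_event, km_estimate, logrank_test, persistence_curve

__all__ = ["fmt_pct", "summarize_cohort", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def fmt_pct(count: int, denominator: int) -> float:
    """Percentage to one decimal, half-up (e.g. 1008/2946 -> 34.2)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= denominator:
        raise ValueError(f"count {count} outside [0, {denominator}]")
    pct = Decimal(100 * count) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _count_row(label: str, count: int, denom: int) -> dict:
    return {
        "row": label,
        "count": int(count),
        "denominator": int(denom),
        "percent": fmt_pct(int(count), int(denom)),
    }


def summarize_cohort(
    cohort: pd.DataFrame, episodes: pd.DataFrame, catalog: DrugCatalog | None = None
) -> dict[str, pd.DataFrame]:
    """Background and outcome summary tables, overall and per onset group.

    Returns a dict of data frames: ``overall`` (counts / denominators /
    percentages), ``by_group`` (the same rows per onset group, with
    chi-square p-values where a 2×k comparison is defined),
    ``first_mtd`` (breakdown of the first MTD; denominator = MTD users
    in the stratum) and ``steroid_days`` (median po/iv prescription
    days with interquartile ranges).
    """
    if cohort.empty:
        raise ValueError("cannot summarize an empty cohort")
    catalog = catalog or default_catalog()
    n = len(cohort)
    groups = {"EO": cohort[cohort["onset_group"] == "EO"],
              "NEO": cohort[cohort["onset_group"] == "NEO"]}

    def indicator_rows(df: pd.DataFrame, denom: int) -> list[dict]:
        rows = [
            _count_row("male", (df["sex"] == "M").sum(), denom),
            _count_row("academic_hospital", df["academic"].sum(), denom),
            _count_row("steroid_use", df["steroid_use"].sum(), denom),
            _count_row("mtd_use", df["mtd_use"].sum(), denom),
            _count_row("mtd_lines_0", (df["mtd_lines"] == 0).sum(), denom),
            _count_row("mtd_lines_1", (df["mtd_lines"] == 1).sum(), denom),
            _count_row("mtd_lines_2plus", (df["mtd_lines"] >= 2).sum(), denom),
            _count_row("surgery", df["surgery"].sum(), denom),
            _count_row("death", df["death"].sum(), denom),
        ]
        return rows

    overall = pd.DataFrame(
        [
            _count_row("elderly_onset", (cohort["onset_group"] == "EO").sum(), n),
            _count_row("non_elderly_onset", (cohort["onset_group"] == "NEO").sum(), n),
        ]
        + indicator_rows(cohort, n)
    )

    by_rows = []
    for label in overall["row"]:
        if label in ("elderly_onset", "non_elderly_onset"):
            continue
        entry: dict = {"row": label}
        counts = {}
        for g, df in groups.items():
            dn = len(df)
            if label == "male":
                c = (df["sex"] == "M").sum()
            elif label == "academic_hospital":
                c = df["academic"].sum()
            elif label.startswith("mtd_lines"):
                c = {"mtd_lines_0": (df["mtd_lines"] == 0).sum(),
                     "mtd_lines_1": (df["mtd_lines"] == 1).sum(),
                     "mtd_lines_2plus": (df["mtd_lines"] >= 2).sum()}[label]
            else:
                c = df[label].sum()
            counts[g] = (int(c), dn)
            entry[f"{g.lower()}_count"] = int(c)
            entry[f"{g.lower()}_denominator"] = dn
            entry[f"{g.lower()}_percent"] = fmt_pct(int(c), dn) if dn else float("nan")
        tab = [[counts["EO"][0], counts["EO"][1] - counts["EO"][0]],
               [counts["NEO"][0], counts["NEO"][1] - counts["NEO"][0]]]
        try:
            _, p = chi_square_compare(tab)
        except ValueError:
            p = float("nan")  # zero-margin cell (e.g. no events in a group)
        entry["chi_square_p"] = p
        by_rows.append(entry)
    by_group = pd.DataFrame(by_rows)

    firsts = first_mtd(episodes, catalog)
    fm_rows = []
    strata = {"overall": cohort, **groups}
    for stratum, df in strata.items():
        users = df[df["mtd_use"] == 1]
        denom = len(users)
        if denom == 0:
            continue
        breakdown = users["mtd_drug"].value_counts()
        for drug_id in sorted(catalog.mtd_ids):
            c = int(breakdown.get(drug_id, 0))
            fm_rows.append({"stratum": stratum, "drug_id": drug_id,
                            "count": c, "denominator": denom,
                            "percent": fmt_pct(c, denom)})
    first_mtd_table = pd.DataFrame(fm_rows)

    sd_rows = []
    for stratum, df in strata.items():
        for route, col in (("po", "steroid_po_days"), ("iv", "steroid_iv_days")):
            vals = df.loc[df[col] > 0, col]
            if len(vals) == 0:
                continue
            med, q1, q3 = median_iqr(vals)
            sd_rows.append({"stratum": stratum, "route": route, "n": len(vals),
                            "median_days": med, "iqr_low": q1, "iqr_high": q3})
    steroid_days = pd.DataFrame(sd_rows)

    return {
        "overall": overall,
        "by_group": by_group,
        "first_mtd": first_mtd_table,
        "steroid_days": steroid_days,
    }


@dataclass
class PipelineConfig:
    """Plain-text (YAML) run configuration."""

    out_dir: str
    claims_dir: str | None = None   # read an existing bundle ...
    simulate: dict | None = None    # ... or generate one (GeneratorConfig fields)
    catalog_path: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def run_pipeline(config: PipelineConfig | str | Path) -> Path:
    """Execute the full analysis and write all artifacts.

    Stages: load-or-simulate claims -> cohort extraction -> episode
    construction -> survival analyses -> regression models -> summary
    tables.  Every stage failure aborts with the stage name.  A run log
    records the seed, package version, and exclusion tally.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.catalog_path is not None:
        if not Path(config.catalog_path).exists():
            raise PipelineError("catalog", f"catalog file not found: {config.catalog_path}")
        catalog = load_catalog(config.catalog_path)
    else:
        catalog = default_catalog()

    try:
        if config.claims_dir is not None:
            bundle = ClaimsBundle.read(config.claims_dir)
        else:
            gen_kwargs = dict(config.simulate or {})
            gen_kwargs.setdefault("seed", config.seed)
            bundle = generate_claims(GeneratorConfig(**gen_kwargs), catalog)
            bundle.write(out / "claims")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("claims", str(exc)) from exc

    try:
        cohort, episodes, tally = build_cohort(bundle, catalog)
    except Exception as exc:
        raise PipelineError("cohort", str(exc)) from exc
    _write_dates(cohort, out / "cohort.tsv")
    _write_dates(episodes, out / "episodes.tsv")

    survival_results = {}
    try:
        for outcome in ("steroid", "mtd", "surgery"):
            tte = extract_time_to_event(cohort, outcome)
            eo = tte[tte["group"] == "EO"]
            neo = tte[tte["group"] == "NEO"]
            frames = []
            for name, grp in (("EO", eo), ("NEO", neo)):
                if len(grp):
                    frames.append(km_estimate(grp["time"], grp["event"], name).to_frame())
            pd.concat(frames).to_csv(out / f"km_{outcome}.tsv", sep="\t", index=False)
            if len(eo) and len(neo):
                stat, p = logrank_test(eo["time"], eo["event"], neo["time"], neo["event"])
                survival_results[outcome] = {"logrank_stat": stat, "p": p}
        firsts = first_mtd(episodes, catalog)
        if len(firsts):
            curves = persistence_curve(
                firsts, cohort.set_index("patient_id")["onset_group"]
            )
            pd.concat([c.to_frame() for c in curves.values()]).to_csv(
                out / "km_persistence.tsv", sep="\t", index=False
            )
    except Exception as exc:
        raise PipelineError("survival", str(exc)) from exc

    model_rows = []
    for outcome in ("steroid", "mtd", "surgery", "death"):
        try:
            res = fit_outcome_model(cohort, outcome)
        except DegenerateFitError as exc:
            logger.warning("model for %s degenerate: %s", outcome, exc)
            continue
        except Exception as exc:
            raise PipelineError("regression", str(exc)) from exc
        tab = res.table.reset_index(names="covariate")
        tab.insert(0, "outcome", outcome)
        tab.insert(1, "family", res.family)
        model_rows.append(tab)
    if model_rows:
        pd.concat(model_rows).to_csv(out / "models.tsv", sep="\t", index=False)

    try:
        tables = summarize_cohort(cohort, episodes, catalog)
    except Exception as exc:
        raise PipelineError("reporting", str(exc)) from exc
    for name, df in tables.items():
        df.to_csv(out / f"summary_{name}.tsv", sep="\t", index=False)

    run_log = {
        "package_version": __version__,
        "seed": config.seed,
        "provenance": bundle.provenance,
        "exclusion_tally": tally.as_dict(),
        "logrank": survival_results,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    return out


def _write_dates(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=False)
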