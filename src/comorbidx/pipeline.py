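"""End-to-end comparison of the four comorbidity adjustment approaches.

Orchestrates: comorbidity filtering and mapping, split-sample design
(random halves), fitting the nine logistic model variants on the
training half, likelihood-ratio tests against the injury+age model,
train/test discrimination (DeLong AUC) and calibration (Hosmer-
Lemeshow, calibration curves), and paired AUC comparisons between
count-based and indicator-based versions of each measure.  Test-half
metrics apply the training coefficients to held-out records
(external-validation style) unless ``refit_on_test`` is set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport, compare_auc, evaluate_predictions
from .indices import ComorbidityMapper, profiles_from_tables
from .models import MODEL_SPECS, FittedModel, ModelSpec, RecoveryModel, lr_test

__all__ = [
    "RunConfig",
    "ComparisonReport",
    "split_dataset",
    "summarize_cohort",
    "prepare_analysis_table",
    "run_comparison",
]

#: paired AUC comparisons reported by default (count vs indicator forms,
#: and chapter count vs six-condition count)
DEFAULT_AUC_PAIRS = (
    ("chapter_count", "chapter_indicators"),
    ("haagsma_count", "haagsma_indicators"),
    ("fci_category", "fci_indicators"),
    ("chapter_count", "haagsma_count"),
)


@dataclass
class RunConfig:
    """Settings for one full comparison run."""

    seed: int = 0
    split_fraction: float = 0.5
    hl_groups: int = 10
    cal_bins: int = 10
    models: tuple[ModelSpec, ...] = MODEL_SPECS
    refit_on_test: bool = False
    haagsma_count_includes_other: bool = False
    map_path: str | None = None
    blocklist_path: str | None = None

    def validate(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if not self.models:
            raise ValueError("model list must be non-empty")


def split_dataset(
    records: pd.DataFrame, seed: int, fraction: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random partition into training (``floor(fraction*n)``) and test.

    Deterministic for a fixed seed; the two halves are disjoint and
    their union is the input.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    perm = np.random.default_rng(seed).permutation(n)
    k = int(np.floor(fraction * n))
    train_idx, test_idx = np.sort(perm[:k]), np.sort(perm[k:])
    return records.iloc[train_idx].copy(), records.iloc[test_idx].copy()


def _block_table(s: pd.Series, block: str) -> pd.DataFrame:
    counts = s.value_counts()
    total = counts.sum()
    return pd.DataFrame(
        {
            "block": block,
            "level": counts.index.astype(str),
            "n": counts.to_numpy(),
            "pct": (100.0 * counts / total).round(1).to_numpy(),
        }
    )


def summarize_cohort(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Cohort summary tables: demographics, burden categories, conditions.

    ``records`` is the patients table joined with comorbidity profiles.
    Percentages are printed to one decimal place.
    """
    if len(records) == 0:
        raise ValueError("no records")

    def _blocks(cols):
        parts = [_block_table(records[c], c) for c in cols if c in records.columns]
        if not parts:
            return pd.DataFrame(columns=["block", "level", "n", "pct"])
        return pd.concat(parts, ignore_index=True)

    demo = _blocks(("age_group", "gender", "mechanism", "injury_group"))
    cats = _blocks(
        ("cci_category", "fci_category", "chapter_category", "haagsma_category")
    )
    score_like = {
        "cci_weight", "fci_score", "chapter_count", "haagsma_count",
        "cci_category", "fci_category", "chapter_category", "haagsma_category",
    }
    flag_cols = [
        c
        for c in records.columns
        if c.split("_")[0] in ("cci", "fci", "chapter", "haagsma")
        and c not in score_like
    ]
    n = len(records)
    cond = pd.DataFrame(
        {
            "condition": flag_cols,
            "n": [int(records[c].sum()) for c in flag_cols],
            "pct": [round(100.0 * records[c].sum() / n, 1) for c in flag_cols],
        }
    )
    return {"demographics": demo, "categories": cats, "conditions": cond}


def prepare_analysis_table(
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    mapper: ComorbidityMapper | None = None,
) -> pd.DataFrame:
    """Join covariates with mapped profiles; keep records with a GOS-E.

    Adds the dichotomised outcome column ``recovered`` (GOS-E 7-8).
    Records without a valid GOS-E are excluded (listwise, before any
    split).  GOS-E 1 (death) raises: the cohort contains survivors to
    discharge only.
    """
    prof = profiles_from_tables(patients, diagnoses, mapper=mapper)
    df = patients.merge(prof.reset_index(), on="patient_id", how="left")
    df = df[df["gose"].notna()].copy()
    gose = df["gose"].astype(int)
    if (gose == 1).any():
        raise ValueError("GOS-E 1 (death) present in survivor cohort")
    if ((gose < 1) | (gose > 8)).any():
        raise ValueError("GOS-E outside 1-8")
    df["recovered"] = (gose >= 7).astype(int)
    return df.reset_index(drop=True)


@dataclass
class ComparisonReport:
    """All outputs of one comparison run."""

    training: list[EvaluationReport]
    test: list[EvaluationReport]
    fits: dict[str, FittedModel]
    auc_comparisons: dict[str, dict]
    summary: dict[str, pd.DataFrame]
    n_train: int
    n_test: int
    seed: int
    refit_on_test: bool

    def _table(self, reports: list[EvaluationReport], with_lr: bool) -> pd.DataFrame:
        rows = []
        for r in reports:
            row = {
                "model": r.model,
                "auc": round(r.auc, 3),
                "auc_ci_low": round(r.auc_ci[0], 3),
                "auc_ci_high": round(r.auc_ci[1], 3),
                "hl_stat": round(r.hl_stat, 2),
                "hl_p": round(r.hl_p, 4),
            }
            if with_lr:
                row["lr_stat"] = None if r.lr_stat is None else round(r.lr_stat, 2)
                row["lr_p"] = None if r.lr_p is None else round(r.lr_p, 6)
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def training_table(self) -> pd.DataFrame:
        return self._table(self.training, with_lr=True)

    @property
    def test_table(self) -> pd.DataFrame:
        return self._table(self.test, with_lr=False)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.training_table.to_csv(out / "training_metrics.csv", index=False)
        self.test_table.to_csv(out / "test_metrics.csv", index=False)
        cal = []
        for split, reports in (("training", self.training), ("test", self.test)):
            for r in reports:
                for mp, ob, sz in r.calibration:
                    cal.append(
                        {
                            "split": split, "model": r.model,
                            "mean_predicted": mp, "observed": ob, "size": sz,
                        }
                    )
        pd.DataFrame(cal).to_csv(out / "calibration_points.csv", index=False)
        for name, df in self.summary.items():
            df.to_csv(out / f"summary_{name}.csv", index=False)
        payload = {
            "seed": self.seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "refit_on_test": self.refit_on_test,
            "hl_df_convention": "groups - 2 in both halves",
            "models": [f.to_dict() for f in self.fits.values()],
            "training": [r.to_dict() for r in self.training],
            "test": [r.to_dict() for r in self.test],
            "auc_comparisons": self.auc_comparisons,
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2, default=float))


def run_comparison(
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    config: RunConfig | None = None,
) -> ComparisonReport:
    """Run the full split-sample model comparison."""
    config = config or RunConfig()
    config.validate()
    mapper = ComorbidityMapper(
        map_path=config.map_path,
        blocklist_path=config.blocklist_path,
        haagsma_count_includes_other=config.haagsma_count_includes_other,
    ).fit()
    data = prepare_analysis_table(patients, diagnoses, mapper=mapper)
    summary = summarize_cohort(data)
    train, test = split_dataset(data, config.seed, config.split_fraction)
    y_train = train["recovered"].to_numpy()
    y_test = test["recovered"].to_numpy()

    fits: dict[str, FittedModel] = {}
    estimators: dict[str, RecoveryModel] = {}
    train_reports: list[EvaluationReport] = []
    test_reports: list[EvaluationReport] = []
    train_preds: dict[str, np.ndarray] = {}

    for spec in config.models:
        est = RecoveryModel(
            comorbidity=spec.comorbidity, include_age=spec.include_age, name=spec.name
        ).fit(train, y_train)
        estimators[spec.name] = est
        fits[spec.name] = est.result_
        train_preds[spec.name] = est.predict_proba(train)[:, 1]

    names = [s.name for s in config.models]
    for spec in config.models:
        rep = evaluate_predictions(
            spec.name, train_preds[spec.name], y_train,
            hl_groups=config.hl_groups, cal_bins=config.cal_bins,
        )
        # LR tests: injury+age vs injury; each comorbidity variant vs
        # injury+age.  The FCI-indicator variant is reported without one.
        if spec.name == "injury_age" and "injury" in fits:
            rep.lr_stat, rep.lr_df, rep.lr_p = lr_test(fits["injury"], fits["injury_age"])
        elif (
            spec.comorbidity is not None
            and spec.name != "fci_indicators"
            and "injury_age" in fits
        ):
            rep.lr_stat, rep.lr_df, rep.lr_p = lr_test(fits["injury_age"], fits[spec.name])
        train_reports.append(rep)

    for spec in config.models:
        if config.refit_on_test:
            est = RecoveryModel(
                comorbidity=spec.comorbidity, include_age=spec.include_age, name=spec.name
            ).fit(test, y_test)
            p = est.predict_proba(test)[:, 1]
        else:
            p = estimators[spec.name].predict_proba(test)[:, 1]
        test_reports.append(
            evaluate_predictions(
                spec.name, p, y_test,
                hl_groups=config.hl_groups, cal_bins=config.cal_bins,
            )
        )

    auc_cmp: dict[str, dict] = {}
    for a, b in DEFAULT_AUC_PAIRS:
        if a in names and b in names:
            chi2, df, p = compare_auc(train_preds[a], train_preds[b], y_train)
            auc_cmp[f"{a}_vs_{b}"] = {"chi2": chi2, "df": df, "p": p}

    return ComparisonReport(
        training=train_reports,
        test=test_reports,
        fits=fits,
        auc_comparisons=auc_cmp,
        summary=summary,
        n_train=len(train),
        n_test=len(test),
        seed=config.seed,
        refit_on_test=config.refit_on_test,
    )
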