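"""Logistic models of 12-month functional recovery.

The outcome is the Glasgow Outcome Scale - Extended (GOS-E, 2-8 in a
survivor cohort) dichotomised at 7: scores 7-8 are "recovered", <7 is
ongoing disability.  Every model contains the injury block (10-level
orthopaedic injury group plus four non-orthopaedic injury indicator
flags); age enters as an 8-level categorical; comorbidity enters as
one of seven alternative adjustment terms (a 0/1/2+ category of one of
the four burden scores, or the per-condition/per-chapter indicator
variables).  Fits are maximum likelihood via Newton-Raphson with a
relative log-likelihood tolerance of 1e-8 (max 100 iterations), and
nested models are compared with likelihood-ratio chi-square tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "dichotomize_gose",
    "ModelSpec",
    "MODEL_SPECS",
    "FittedModel",
    "build_design",
    "fit_logistic",
    "lr_test",
    "RecoveryModel",
    "SeparationError",
    "INJURY_FLAGS",
    "COMORBIDITY_TERMS",
]

INJURY_FLAGS = ("head_injury", "rib_fractures", "organ_injury", "burns")

CHAPTER_FLAG_COLS = [
    f"chapter_{ch.lower()}"
    for ch in (
        "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI",
        "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XIX",
    )
]


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


def dichotomize_gose(gose: int) -> bool:
    """True iff GOS-E 7-8 ("recovered"); <7 is ongoing disability.

    GOS-E 1 codes death and cannot occur in a survivors-to-discharge
    cohort; it and out-of-range values raise ``ValueError``.
    """
    g = int(gose)
    if g == 1:
        raise ValueError("GOS-E 1 (death) in survivor cohort")
    if not 2 <= g <= 8:
        raise ValueError(f"GOS-E must be in 1-8, got {gose}")
    return g >= 7


@dataclass(frozen=True)
class ModelSpec:
    """One model variant: injury block, optional age, comorbidity term."""

    name: str
    include_age: bool = True
    comorbidity: str | None = None  # key of COMORBIDITY_TERMS or None


#: comorbidity term -> (kind, column or columns)
COMORBIDITY_TERMS: dict[str, tuple[str, object]] = {
    "chapter_count_category": ("category", "chapter_category"),
    "chapter_indicators": ("indicators", CHAPTER_FLAG_COLS),
    "haagsma_count_category": ("category", "haagsma_category"),
    "haagsma_indicators": ("indicators", "haagsma_flags"),  # resolved at build
    "cci_category": ("category", "cci_category"),
    "fci_category": ("category", "fci_category"),
    "fci_indicators": ("indicators", "fci_flags"),
}

#: the nine model variants, in reporting order
MODEL_SPECS: tuple[ModelSpec, ...] = (
    ModelSpec("injury", include_age=False),
    ModelSpec("injury_age"),
    ModelSpec("chapter_count", comorbidity="chapter_count_category"),
    ModelSpec("chapter_indicators", comorbidity="chapter_indicators"),
    ModelSpec("haagsma_count", comorbidity="haagsma_count_category"),
    ModelSpec("haagsma_indicators", comorbidity="haagsma_indicators"),
    ModelSpec("cci_category", comorbidity="cci_category"),
    ModelSpec("fci_category", comorbidity="fci_category"),
    ModelSpec("fci_indicators", comorbidity="fci_indicators"),
)


def _indicator_cols(df: pd.DataFrame, key) -> list[str]:
    if key == "haagsma_flags":
        cols = [c for c in df.columns if c.startswith("haagsma_")]
        return [
            c
            for c in cols
            if c not in ("haagsma_count", "haagsma_category")
        ]
    if key == "fci_flags":
        return [
            c
            for c in df.columns
            if c.startswith("fci_") and c not in ("fci_score", "fci_category")
        ]
    return list(key)


def _dummies(
    s: pd.Series, name: str, reference: str | None
) -> tuple[pd.DataFrame, str]:
    s = s.astype(str)
    levels = s.value_counts()
    if reference is None:
        reference = levels.index[0]  # most frequent level
    seen = set(levels.index)
    cols = {}
    for lev in sorted(seen - {reference}):
        cols[f"{name}[{lev}]"] = (s == lev).astype(float)
    return pd.DataFrame(cols, index=s.index), reference


def build_design(
    df: pd.DataFrame,
    spec: ModelSpec,
    references: dict[str, str] | None = None,
    columns: list[str] | None = None,
    drop_constant: bool = False,
    known_dropped: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str], list[str]]:
    """Build the dummy-coded design matrix (with intercept) for ``spec``.

    ``df`` holds covariates and profile columns, one row per patient.
    Reference levels default to the most frequent level of each
    categorical and are returned for reuse at prediction time; if
    ``references`` is given, an unseen category level raises.
    ``columns`` pins the output column set (prediction path).
    ``drop_constant`` omits zero-variance non-intercept columns (an
    indicator with no cases in the fitting half is inestimable and is
    dropped, as standard fitting software does); dropped names are
    returned third.
    """
    refs_in = references or {}
    refs_out: dict[str, str] = {}
    indicator_cols: list[str] = []
    parts = [pd.Series(1.0, index=df.index, name="const").to_frame()]

    d, r = _dummies(df["injury_group"], "injury_group", refs_in.get("injury_group"))
    refs_out["injury_group"] = r
    parts.append(d)
    parts.append(df[list(INJURY_FLAGS)].astype(float))
    indicator_cols += list(INJURY_FLAGS)

    if spec.include_age:
        d, r = _dummies(df["age_group"], "age_group", refs_in.get("age_group"))
        refs_out["age_group"] = r
        parts.append(d)

    if spec.comorbidity is not None:
        kind, key = COMORBIDITY_TERMS[spec.comorbidity]
        if kind == "category":
            d, r = _dummies(df[key], key, refs_in.get(key, "0"))
            refs_out[key] = r
            parts.append(d)
        else:
            cols = _indicator_cols(df, key)
            parts.append(df[cols].astype(float))
            indicator_cols += cols

    X = pd.concat(parts, axis=1)
    dropped: list[str] = []
    if columns is not None:
        extra = set(X.columns) - set(columns)
        # a pre-specified column set may legitimately omit indicator
        # columns, or dummies dropped at fit time; anything else extra
        # is an unseen category level
        unseen = extra - set(indicator_cols) - set(known_dropped or [])
        if unseen:
            raise ValueError(f"unseen category levels at prediction: {sorted(unseen)}")
        dropped = sorted(extra)
        X = X.reindex(columns=columns, fill_value=0.0)
    elif drop_constant:
        arr = X.to_numpy()
        const = [
            c
            for i, c in enumerate(X.columns)
            if c != "const" and np.ptp(arr[:, i]) == 0.0
        ]
        if const:
            dropped = const
            X = X.drop(columns=const)
    return X, refs_out, dropped


@dataclass
class FittedModel:
    """Maximum-likelihood logistic fit results."""

    spec: ModelSpec
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    n: int
    converged: bool
    references: dict[str, str] = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.params.index)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.values)), index=self.params.index)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        lp = X[self.columns].to_numpy() @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-lp))

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "n": int(self.n),
            "log_likelihood": float(self.llf),
            "converged": bool(self.converged),
            "references": self.references,
            "coefficients": [
                {"term": t, "estimate": float(b), "se": float(s)}
                for t, b, s in zip(self.columns, self.params, self.bse)
            ],
        }


def fit_logistic(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: ModelSpec | None = None,
    references: dict[str, str] | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> FittedModel:
    """Fit recovery ~ X by maximum likelihood (Newton-Raphson).

    Raises :class:`SeparationError` on single-class outcomes or
    (quasi-)complete separation, and ``ValueError`` on a rank-deficient
    design, naming the offending column where identifiable.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and outcome lengths differ")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than design columns")
    if y.min() == y.max():
        raise SeparationError("outcomes are single-class; model is inestimable")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify a dependent column for the error message
        culprit = _rank_deficient_column(X)
        raise ValueError(f"design matrix is rank deficient (column {culprit!r})")
    try:
        res = sm.Logit(y, X).fit(
            method="newton", maxiter=maxiter, tol=tol, disp=0, warn_convergence=False
        )
    except (PerfectSeparationError, np.linalg.LinAlgError) as e:
        raise SeparationError(f"logistic fit failed: {e}") from e
    params = pd.Series(np.asarray(res.params), index=X.columns)
    if np.abs(params).max() > 20:
        worst = params.abs().idxmax()
        raise SeparationError(
            f"quasi-complete separation suspected (column {worst!r}, "
            f"coefficient {params[worst]:.1f})"
        )
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=X.columns, columns=X.columns)
    return FittedModel(
        spec=spec or ModelSpec("custom"),
        params=params,
        cov=cov,
        llf=float(res.llf),
        n=int(X.shape[0]),
        converged=bool(res.mle_retvals.get("converged", True)),
        references=references or {},
    )


def _rank_deficient_column(X: pd.DataFrame) -> str:
    cols = list(X.columns)
    for i in range(1, len(cols) + 1):
        if np.linalg.matrix_rank(X.iloc[:, :i].to_numpy()) < i:
            return cols[i - 1]
    return "?"


def lr_test(nested: FittedModel, full: FittedModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of ``full`` against ``nested``.

    Returns (chi-square statistic, degrees of freedom, p-value).
    Requires the nested model's columns to be a subset of the full
    model's and both fits to use the same records.
    """
    if not set(nested.columns) <= set(full.columns):
        raise ValueError("models are not nested (column sets)")
    if nested.n != full.n:
        raise ValueError("models fitted on different record counts")
    df = len(full.columns) - len(nested.columns)
    stat = max(0.0, 2.0 * (full.llf - nested.llf))
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


class RecoveryModel(BaseEstimator, ClassifierMixin):
    """scikit-learn estimator for one recovery model variant.

    Parameters
    ----------
    comorbidity : str or None
        One of :data:`COMORBIDITY_TERMS` keys, or None for no
        comorbidity adjustment.
    include_age : bool, default True
        Whether the 8-level age-group block enters the model.
    tol, maxiter : Newton-Raphson convergence settings.

    Fitted attributes: ``coef_`` (pd.Series on the log-odds scale),
    ``cov_``, ``llf_``, ``n_obs_``, ``references_`` (category reference
    levels), ``columns_``, ``converged_``, ``result_`` (the underlying
    :class:`FittedModel`).
    """

    def __init__(
        self,
        comorbidity: str | None = None,
        include_age: bool = True,
        name: str | None = None,
        tol: float = 1e-8,
        maxiter: int = 100,
    ):
        self.comorbidity = comorbidity
        self.include_age = include_age
        self.name = name
        self.tol = tol
        self.maxiter = maxiter

    def _spec(self) -> ModelSpec:
        name = self.name or (self.comorbidity or ("injury_age" if self.include_age else "injury"))
        return ModelSpec(name, include_age=self.include_age, comorbidity=self.comorbidity)

    def fit(self, X: pd.DataFrame, y) -> "RecoveryModel":
        spec = self._spec()
        y = np.asarray(y, dtype=float)
        design, refs, dropped = build_design(X, spec, drop_constant=True)
        # a rare indicator or dummy whose few carriers share one outcome
        # quasi-separates the likelihood; omit it (for a dummy this
        # collapses the sparse level into the reference, as standard
        # software does) rather than report a divergent coefficient
        separating = []
        for c in design.columns:
            if c == "const":
                continue
            v = design[c].to_numpy()
            if set(np.unique(v)) <= {0.0, 1.0} and v.any():
                ysub = y[v == 1.0]
                if ysub.min() == ysub.max():
                    separating.append(c)
        if separating:
            design = design.drop(columns=separating)
            dropped = dropped + separating
        res = fit_logistic(
            design, y, spec=spec, references=refs, tol=self.tol, maxiter=self.maxiter
        )
        self.result_ = res
        self.dropped_ = dropped
        self.coef_ = res.params
        self.cov_ = res.cov
        self.llf_ = res.llf
        self.n_obs_ = res.n
        self.references_ = refs
        self.columns_ = res.columns
        self.converged_ = res.converged
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        design, _, _ = build_design(
            X, self._spec(), references=self.references_, columns=self.columns_,
            known_dropped=getattr(self, "dropped_", None),
        )
        p = self.result_.predict(design)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
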