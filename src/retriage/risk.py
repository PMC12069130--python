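"""Mixed-effect logistic STDR risk models over qualifying appointments.

Four nested covariate sets predict an STDR outcome within the next 590
days of a qualifying appointment (an R0M0 visit directly following an
R0M0 visit), with the person fitted as a random intercept:

1. age, diabetes duration, type 1 indicator, prior non-attendance;
2. set 1 plus ethnic group;
3. set 1 plus median HbA1c, SD of HbA1c and diastolic BP;
4. set 3 plus ethnic group.

Missing measurement summaries are imputed with fixed population medians:
51 mmol/mol (HbA1c median), 6.2 mmol/mol (HbA1c SD), 76 mmHg (diastolic),
130 mmHg (systolic); a single observed HbA1c value supplies the median
while its SD is imputed.  Smoking is excluded throughout.

Triage predictions are population level (random intercept at zero), and
the probability threshold is calibrated so the highest 20% of predicted
risks over qualifying appointments are flagged for annual recall.
"""
from __future__ import annotations

import datetime as dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .eligibility import EligibleHistory, qualifying_appointments
from .mixedlogit import MixedLogit, MixedLogitResults
from .types import ETHNICITIES, ScreeningHistory

# fixed imputation constants (population medians of the source programme)
HBA1C_MEDIAN_IMPUTE = 51.0
HBA1C_SD_IMPUTE = 6.2
DBP_IMPUTE = 76.0
SBP_IMPUTE = 130.0

ETH_DUMMIES = [f"eth_{e}" for e in ETHNICITIES[1:]]  # white is the reference

_COVARIATE_SETS: dict[int, list[str]] = {
    1: ["age", "duration", "type1", "prior_dna"],
    2: ["age", "duration", "type1", "prior_dna", "ethnicity"],
    3: ["age", "duration", "type1", "prior_dna", "hba1c_median", "hba1c_sd", "dbp"],
    4: ["age", "duration", "type1", "prior_dna", "hba1c_median", "hba1c_sd", "dbp", "ethnicity"],
}
_CONTINUOUS = ("age", "duration", "hba1c_median", "hba1c_sd", "dbp")


@dataclass(frozen=True)
class MeasurementSummary:
    """Per-person measurement summary at a reference date, with imputation flags."""

    median_hba1c: float
    sd_hba1c: float
    dbp: float
    sbp: float
    imputed_median_hba1c: bool = False
    imputed_sd_hba1c: bool = False
    imputed_dbp: bool = False
    imputed_sbp: bool = False


def summarise_measurements(history: ScreeningHistory, at_date: dt.date) -> MeasurementSummary:
    """Summarise measurement series using values dated before ``at_date``."""
    hba1c = [v for d, v in history.hba1c_series if d < at_date]
    if len(hba1c) == 0:
        med, sd, imp_med, imp_sd = HBA1C_MEDIAN_IMPUTE, HBA1C_SD_IMPUTE, True, True
    elif len(hba1c) == 1:
        med, sd, imp_med, imp_sd = hba1c[0], HBA1C_SD_IMPUTE, False, True
    else:
        med = float(np.median(hba1c))
        sd = float(np.std(hba1c, ddof=1))
        imp_med = imp_sd = False
    dbp_vals = [v for d, v in history.dbp_series if d < at_date]
    sbp_vals = [v for d, v in history.sbp_series if d < at_date]
    dbp = float(np.median(dbp_vals)) if dbp_vals else DBP_IMPUTE
    sbp = float(np.median(sbp_vals)) if sbp_vals else SBP_IMPUTE
    return MeasurementSummary(
        median_hba1c=float(med), sd_hba1c=float(sd), dbp=dbp, sbp=sbp,
        imputed_median_hba1c=imp_med, imputed_sd_hba1c=imp_sd,
        imputed_dbp=not dbp_vals, imputed_sbp=not sbp_vals,
    )


def covariate_row(eligible: EligibleHistory, index: int) -> dict:
    """Covariates at one appointment of an eligible history."""
    hist = eligible.history
    person = hist.person
    date = hist.appointments[index].date
    raw = eligible.raw or hist
    prior_dna = any(not a.attended and a.date < date for a in raw.appointments)
    meas = summarise_measurements(hist, date)
    row = {
        "person_id": person.id,
        "date": date,
        "age": person.age_years(date),
        "duration": person.duration_years(date),
        "type1": float(person.diabetes_type == "type1"),
        "prior_dna": float(prior_dna),
        "ethnicity": person.ethnicity,
        "hba1c_median": meas.median_hba1c,
        "hba1c_sd": meas.sd_hba1c,
        "dbp": meas.dbp,
        "sbp": meas.sbp,
    }
    for e, col in zip(ETHNICITIES[1:], ETH_DUMMIES):
        row[col] = float(person.ethnicity == e)
    return row


def build_training_table(
    eligibles: Sequence[EligibleHistory], outcome_window_days: int = 590
) -> pd.DataFrame:
    """One row per qualifying appointment with covariates and the binary
    outcome: any STDR appointment within ``outcome_window_days`` after it."""
    rows = []
    for e in eligibles:
        retained = e.retained()
        stdr_dates = [a.date for a in retained if a.is_stdr]
        for j in qualifying_appointments(e):
            row = covariate_row(e, j)
            date = retained[j].date
            row["outcome"] = float(
                any(0 < (d - date).days <= outcome_window_days for d in stdr_dates)
            )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fractional polynomial transform selection

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class FPTransform:
    """Fractional-polynomial transform: powers over a shifted covariate.

    Power 0 denotes the natural logarithm; a repeated power (p, p) denotes
    the pair (x^p, x^p * log x), following the usual FP convention.
    """

    powers: tuple[float, ...] = (1.0,)
    shift: float = 0.0

    def design(self, x: np.ndarray) -> np.ndarray:
        z = np.asarray(x, dtype=float) + self.shift
        cols = []
        prev: Optional[float] = None
        for p in self.powers:
            base = np.log(z) if p == 0.0 else z**p
            if prev is not None and p == prev:
                base = base * np.log(z)
            cols.append(base)
            prev = p
        return np.column_stack(cols)

    @property
    def is_linear(self) -> bool:
        return self.powers == (1.0,)


def _deviance(y: np.ndarray, X: np.ndarray) -> float:
    model = sm.GLM(y, sm.add_constant(X, has_constant="add"), family=sm.families.Binomial())
    return float(model.fit().deviance)


def select_fp_transform(
    table: pd.DataFrame,
    covariate: str,
    outcome: str = "outcome",
    alpha: float = 0.05,
) -> FPTransform:
    """Closed-test FP1/FP2 search over powers {-2,-1,-0.5,0,0.5,1,2,3}.

    Uses plain logistic deviances for the selection step.  The function
    compares the best two-term FP against the null, then against the
    linear term, then against the best one-term FP, each at ``alpha``;
    linear is retained whenever a nonlinear shape is not supported (the
    covariate itself is never dropped, because the covariate sets are
    fixed by design).
    """
    x = table[covariate].to_numpy(dtype=float)
    y = table[outcome].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        warnings.warn(f"covariate {covariate!r} is constant; keeping linear term")
        return FPTransform((1.0,))
    shift = 0.0 if x.min() > 0 else float(-x.min() + 1.0)

    dev_null = _deviance(y, np.empty((len(y), 0)))
    candidates1 = {(p,): FPTransform((p,), shift) for p in FP_POWERS}
    dev1 = {k: _deviance(y, t.design(x)) for k, t in candidates1.items()}
    best1 = min(dev1, key=dev1.get)
    candidates2 = {
        (p1, p2): FPTransform((p1, p2), shift)
        for i, p1 in enumerate(FP_POWERS)
        for p2 in FP_POWERS[i:]
    }
    dev2 = {k: _deviance(y, t.design(x)) for k, t in candidates2.items()}
    best2 = min(dev2, key=dev2.get)
    dev_linear = dev1[(1.0,)]

    def significant(dev_low: float, dev_high: float, df: int) -> bool:
        return chi2.sf(max(dev_high - dev_low, 0.0), df) < alpha

    if not significant(dev2[best2], dev_null, 4):
        return FPTransform((1.0,), shift)
    if not significant(dev2[best2], dev_linear, 3):
        return FPTransform((1.0,), shift)
    if not significant(dev2[best2], dev1[best1], 2):
        return candidates1[best1]
    return candidates2[best2]


# ---------------------------------------------------------------------------
# model specification and fitting


@dataclass
class ModelSpec:
    """Covariate set 1-4 plus per-continuous-covariate FP transforms."""

    covariate_set: int = 2
    transforms: dict[str, FPTransform] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.covariate_set not in _COVARIATE_SETS:
            raise ValueError("covariate_set must be 1, 2, 3 or 4")
        unknown = set(self.transforms) - set(_CONTINUOUS)
        if unknown:
            raise ValueError(f"transforms given for non-continuous covariates {unknown}")

    @property
    def covariates(self) -> list[str]:
        return list(_COVARIATE_SETS[self.covariate_set])

    @property
    def includes_ethnicity(self) -> bool:
        return "ethnicity" in self.covariates

    def transform_for(self, cov: str) -> FPTransform:
        return self.transforms.get(cov, FPTransform())


def _design_matrix(spec: ModelSpec, table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(table))]
    names = ["intercept"]
    for cov in spec.covariates:
        if cov == "ethnicity":
            for col in ETH_DUMMIES:
                if col not in table.columns:
                    raise ValueError(f"missing covariate: {col}")
                cols.append(table[col].to_numpy(dtype=float)[:, None])
                names.append(col)
            continue
        if cov not in table.columns:
            raise ValueError(f"missing covariate: {cov}")
        x = table[cov].to_numpy(dtype=float)
        if cov in _CONTINUOUS:
            tr = spec.transform_for(cov)
            block = tr.design(x)
            if block.shape[1] == 1 and tr.is_linear:
                names.append(cov)
            else:
                names.extend(f"{cov}__fp{i+1}" for i in range(block.shape[1]))
            cols.append(block)
        else:
            cols.append(x[:, None])
            names.append(cov)
    return np.column_stack(cols), names


def _design_row(spec: ModelSpec, row: dict) -> tuple[np.ndarray, list[str]]:
    """Single-row design vector without the DataFrame round trip."""
    vals = [1.0]
    names = ["intercept"]
    for cov in spec.covariates:
        if cov == "ethnicity":
            for col in ETH_DUMMIES:
                if col not in row:
                    raise ValueError(f"missing covariate: {col}")
                vals.append(float(row[col]))
                names.append(col)
            continue
        if cov not in row:
            raise ValueError(f"missing covariate: {cov}")
        x = float(row[cov])
        if cov in _CONTINUOUS:
            tr = spec.transform_for(cov)
            block = tr.design(np.array([x]))[0]
            if len(block) == 1 and tr.is_linear:
                names.append(cov)
            else:
                names.extend(f"{cov}__fp{i+1}" for i in range(len(block)))
            vals.extend(block.tolist())
        else:
            vals.append(x)
            names.append(cov)
    return np.asarray(vals), names


class STDRRiskModel:
    """Model object: a covariate set bound to a training table.

    ``fit()`` returns a :class:`RiskModelFit` results object.
    """

    def __init__(self, table: pd.DataFrame, spec: ModelSpec | int):
        self.spec = ModelSpec(spec) if isinstance(spec, int) else spec
        self.table = table.reset_index(drop=True)
        self.exog, self.exog_names = _design_matrix(self.spec, self.table)

    @classmethod
    def from_training_table(
        cls,
        table: pd.DataFrame,
        covariate_set: int = 2,
        select_transforms: bool = False,
        alpha: float = 0.05,
    ) -> "STDRRiskModel":
        transforms = {}
        if select_transforms:
            base = _COVARIATE_SETS[covariate_set]
            for cov in base:
                if cov in _CONTINUOUS:
                    tr = select_fp_transform(table, cov, alpha=alpha)
                    if not tr.is_linear:
                        transforms[cov] = tr
        return cls(table, ModelSpec(covariate_set, transforms))

    def fit(self, n_quad: int = 51, **kwargs) -> "RiskModelFit":
        ml = MixedLogit(
            self.table["outcome"].to_numpy(dtype=float),
            self.exog,
            self.table["person_id"].to_numpy(),
            exog_names=self.exog_names,
            n_quad=n_quad,
        )
        res = ml.fit(**kwargs)
        return RiskModelFit(self.spec, res, self.table)


class RiskModelFit:
    """Results object: coefficients, random-intercept variance, threshold."""

    def __init__(
        self,
        spec: ModelSpec,
        results: MixedLogitResults,
        training_table: Optional[pd.DataFrame] = None,
        threshold_p: Optional[float] = None,
    ):
        self.spec = spec
        self.results = results
        self.params = results.params
        self.bse = results.bse
        self.re_sd = results.re_sd
        self.llf = results.llf
        self.converged = results.converged
        self.threshold_p = threshold_p
        self._training_table = training_table
        if training_table is not None:
            self.training_summary = {
                "n_appointments": int(len(training_table)),
                "n_events": int(training_table["outcome"].sum()),
                "n_people": int(training_table["person_id"].nunique()),
            }
        else:
            self.training_summary = {}

    @property
    def re_variance(self) -> float:
        return self.re_sd**2

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Population-level 2-year STDR probability for each row."""
        X, names = _design_matrix(self.spec, table)
        beta = self.params.reindex(names)
        if beta.isna().any():
            missing = beta.index[beta.isna()].tolist()
            raise ValueError(f"fit lacks coefficients for {missing}")
        eta = X @ beta.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_row(self, row: dict) -> float:
        x, names = _design_row(self.spec, row)
        beta = self.params.reindex(names)
        if beta.isna().any():
            missing = beta.index[beta.isna()].tolist()
            raise ValueError(f"fit lacks coefficients for {missing}")
        return float(1.0 / (1.0 + np.exp(-float(x @ beta.to_numpy()))))

    def predict_history(self, eligible: EligibleHistory, index: int) -> float:
        cache = eligible.__dict__.setdefault("_risk_cache", {})
        key = (id(self), index)
        if key not in cache:
            cache[key] = self.predict_row(covariate_row(eligible, index))
        return cache[key]

    def calibrate_threshold(
        self, table: Optional[pd.DataFrame] = None, flag_fraction: float = 0.20
    ) -> float:
        """Set ``threshold_p`` so the top ``flag_fraction`` of predicted
        risks over qualifying-appointment rows are flagged (ties flag as
        seen downstream)."""
        if table is None:
            table = self._training_table
        if table is None:
            raise ValueError("no training table available for calibration")
        self.threshold_p = calibrate_threshold(self, table, flag_fraction)
        return self.threshold_p

    def summary(self) -> str:
        head = f"STDR risk model (covariate set {self.spec.covariate_set})"
        tail = ""
        if self.threshold_p is not None:
            tail = f"\ncalibrated probability threshold: {self.threshold_p:.6f}"
        return head + "\n" + self.results.summary() + tail

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "covariate_set": self.spec.covariate_set,
            "transforms": {
                cov: {"powers": list(tr.powers), "shift": tr.shift}
                for cov, tr in self.spec.transforms.items()
            },
            "coefficients": self.params.to_dict(),
            "standard_errors": self.bse.to_dict(),
            "re_variance": self.re_variance,
            "log_likelihood": self.llf,
            "threshold_p": self.threshold_p,
            "training_summary": self.training_summary,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModelFit":
        spec = ModelSpec(
            d["covariate_set"],
            {
                cov: FPTransform(tuple(t["powers"]), t["shift"])
                for cov, t in d.get("transforms", {}).items()
            },
        )
        fit = cls.__new__(cls)
        fit.spec = spec
        fit.results = None
        fit.params = pd.Series(d["coefficients"], name="coef")
        fit.bse = pd.Series(d.get("standard_errors", {}), name="se")
        fit.re_sd = float(d["re_variance"]) ** 0.5
        fit.llf = d.get("log_likelihood", float("nan"))
        fit.converged = True
        fit.threshold_p = d.get("threshold_p")
        fit._training_table = None
        fit.training_summary = d.get("training_summary", {})
        return fit

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModelFit":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_mixed_logit(table: pd.DataFrame, spec: ModelSpec | int, **kwargs) -> RiskModelFit:
    """Fit one of the four covariate-set models on a training table."""
    return STDRRiskModel(table, spec).fit(**kwargs)


def calibrate_threshold(
    fit: RiskModelFit, table: pd.DataFrame, flag_fraction: float = 0.20
) -> float:
    """Lower (type-1) empirical quantile of predicted risk at 1 - flag_fraction."""
    if not 0.0 < flag_fraction < 1.0:
        raise ValueError("flag_fraction must be in (0, 1)")
    p = np.sort(fit.predict(table))
    n = len(p)
    k = int(np.ceil(n * (1.0 - flag_fraction)))
    k = min(max(k, 1), n)
    return float(p[k - 1])


def predict_risk(fit: RiskModelFit, covariate_row: dict | pd.Series) -> float:
    """Inverse-logit of the population-level linear predictor for one row."""
    return fit.predict_row(dict(covariate_row))
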