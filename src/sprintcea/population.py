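"""Survey-style person-level populations: generation, CSV I/O, weighted estimation.

The generator emulates the joint covariate structure of a national
health-and-retirement style survey: sex-stratified marginals for the
continuous risk factors, a Gaussian copula carrying the rank correlations
(most importantly age-SBP), a logistic model linking age and SBP to
antihypertensive-treatment status, and positive, skewed survey weights
normalized to mean 1 so that weighted proportions scale directly to a
"represented millions" factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, EstimateError, FormatError, RowError

__all__ = [
    "Individual",
    "PopulationSpec",
    "SexMarginals",
    "TreatmentModel",
    "WeightModel",
    "generate_population",
    "read_population",
    "write_population",
    "weighted_proportion",
    "ReadResult",
    "WeightedEstimate",
    "CONTINUOUS_COVARIATES",
    "default_spec",
]

CONTINUOUS_COVARIATES = ("age", "sbp", "dbp", "total_chol", "hdl_chol", "creatinine")

_CLIP = {
    "age": (45.0, 105.0),
    "sbp": (70.0, 250.0),
    "dbp": (40.0, 150.0),
    "total_chol": (80.0, 400.0),
    "hdl_chol": (15.0, 120.0),
    "creatinine": (0.3, 12.0),
}

REQUIRED_COLUMNS = (
    "id",
    "age",
    "sex",
    "sbp",
    "dbp",
    "on_bp_treatment",
    "smoker",
    "total_chol",
    "hdl_chol",
    "hist_chd",
    "hist_stroke",
    "hist_hf",
    "diabetes",
    "esrd",
    "survey_weight",
)
OPTIONAL_COLUMNS = ("n_bp_med_classes", "egfr", "creatinine")
_FLAG_COLUMNS = (
    "on_bp_treatment",
    "smoker",
    "hist_chd",
    "hist_stroke",
    "hist_hf",
    "diabetes",
    "esrd",
)


@dataclass
class Individual:
    """One survey respondent: the atom of screening and simulation."""

    id: str
    age: int
    sex: str  # "male" | "female"
    sbp: float
    dbp: float
    on_bp_treatment: bool
    smoker: bool
    total_chol: float
    hdl_chol: float
    hist_chd: bool
    hist_stroke: bool
    hist_hf: bool
    diabetes: bool
    esrd: bool
    survey_weight: float
    n_bp_med_classes: Optional[int] = None
    egfr: Optional[float] = None
    creatinine: Optional[float] = None

    def validate(self) -> None:
        if not 45 <= self.age <= 105:
            raise ValueError(f"{self.id}: age {self.age} outside [45, 105]")
        if not 70 <= self.sbp <= 250:
            raise ValueError(f"{self.id}: sbp {self.sbp} outside [70, 250]")
        if self.hdl_chol >= self.total_chol:
            raise ValueError(f"{self.id}: HDL must be below total cholesterol")
        if self.survey_weight <= 0:
            raise ValueError(f"{self.id}: survey weight must be positive")
        if self.egfr is not None and self.egfr <= 0:
            raise ValueError(f"{self.id}: eGFR must be positive when present")
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.id}: sex must be 'male' or 'female'")


@dataclass
class SexMarginals:
    """Means/SDs for continuous covariates and prevalences for flags, one sex."""

    means: dict = field(
        default_factory=lambda: {
            "age": 59.0,
            "sbp": 132.0,
            "dbp": 78.0,
            "total_chol": 195.0,
            "hdl_chol": 50.0,
            "creatinine": 0.9,
        }
    )
    sds: dict = field(
        default_factory=lambda: {
            "age": 10.0,
            "sbp": 20.0,
            "dbp": 11.0,
            "total_chol": 38.0,
            "hdl_chol": 12.0,
            "creatinine": 0.25,
        }
    )
    prevalences: dict = field(
        default_factory=lambda: {
            "smoker": 0.30,
            "hist_chd": 0.08,
            "hist_stroke": 0.03,
            "hist_hf": 0.015,
            "diabetes": 0.10,
            "esrd": 0.002,
        }
    )


@dataclass
class TreatmentModel:
    """Logistic model for on_bp_treatment given age and SBP."""

    intercept: float = -2.2
    age_coef: float = 0.03  # per year above 60
    sbp_coef: float = 0.04  # per mm Hg above 140


@dataclass
class WeightModel:
    """Log-normal survey weights, mean-normalized to 1."""

    sigma: float = 0.5


@dataclass
class PopulationSpec:
    """Everything needed to generate one synthetic population."""

    n: int = 1000
    seed: int = 0
    male_fraction: float = 0.48
    marginals: dict = field(
        default_factory=lambda: {"male": SexMarginals(), "female": SexMarginals()}
    )
    correlation: Optional[np.ndarray] = None  # rank correlations, CONTINUOUS order
    treatment_model: TreatmentModel = field(default_factory=TreatmentModel)
    weight_model: WeightModel = field(default_factory=WeightModel)

    def __post_init__(self):
        if self.correlation is None:
            self.correlation = _default_rank_correlation()
        self.correlation = np.asarray(self.correlation, dtype=float)

    def validate(self) -> None:
        k = len(CONTINUOUS_COVARIATES)
        c = self.correlation
        if c.shape != (k, k):
            raise ConfigurationError(f"correlation matrix must be {k}x{k}")
        if not np.allclose(c, c.T):
            raise ConfigurationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ConfigurationError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise ConfigurationError("correlation matrix is not positive semi-definite")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigurationError("male_fraction must lie in [0, 1]")
        for sex, m in self.marginals.items():
            for cov in CONTINUOUS_COVARIATES:
                if m.sds[cov] < 0:
                    raise ConfigurationError(f"{sex}/{cov}: SD must be >= 0")
            for flag, p in m.prevalences.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"{sex}/{flag}: prevalence outside [0, 1]")
        if self.weight_model.sigma < 0:
            raise ConfigurationError("weight sigma must be >= 0")


def _default_rank_correlation() -> np.ndarray:
    k = len(CONTINUOUS_COVARIATES)
    c = np.eye(k)

    def set_(a, b, r):
        i, j = CONTINUOUS_COVARIATES.index(a), CONTINUOUS_COVARIATES.index(b)
        c[i, j] = c[j, i] = r

    set_("age", "sbp", 0.30)
    set_("age", "creatinine", 0.20)
    set_("sbp", "dbp", 0.60)
    set_("total_chol", "hdl_chol", 0.15)
    return c


def default_spec(n: int = 1000, seed: int = 0) -> PopulationSpec:
    """A ready-to-use spec with survey-like defaults."""
    return PopulationSpec(n=n, seed=seed)


def _rank_to_pearson(rank_corr: np.ndarray) -> np.ndarray:
    """Convert Spearman rank correlations to the Gaussian-copula Pearson matrix."""
    p = 2.0 * np.sin(np.pi * rank_corr / 6.0)
    np.fill_diagonal(p, 1.0)
    # repair tiny negative eigenvalues introduced by the transform
    w, v = np.linalg.eigh(p)
    if w.min() < 0:
        w = np.clip(w, 1e-10, None)
        p = (v * w) @ v.T
        d = np.sqrt(np.diag(p))
        p = p / np.outer(d, d)
    return p


def generate_population(spec: PopulationSpec) -> list[Individual]:
    """Draw ``spec.n`` Individuals; identical seed implies identical output."""
    spec.validate()
    if spec.n == 0:
        return []
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    sexes = np.where(rng.random(n) < spec.male_fraction, "male", "female")
    pearson = _rank_to_pearson(spec.correlation)
    chol = np.linalg.cholesky(pearson + 1e-12 * np.eye(pearson.shape[0]))
    z = rng.standard_normal((n, len(CONTINUOUS_COVARIATES))) @ chol.T

    cont = {}
    for j, cov in enumerate(CONTINUOUS_COVARIATES):
        x = np.empty(n)
        for sex in ("male", "female"):
            mask = sexes == sex
            m = spec.marginals[sex]
            x[mask] = m.means[cov] + m.sds[cov] * z[mask, j]
        lo, hi = _CLIP[cov]
        cont[cov] = np.clip(x, lo, hi)
    cont["age"] = np.rint(cont["age"]).astype(int)
    # keep the HDL < total cholesterol invariant
    cont["hdl_chol"] = np.minimum(cont["hdl_chol"], cont["total_chol"] - 5.0)

    flags = {}
    for flag in ("smoker", "hist_chd", "hist_stroke", "hist_hf", "diabetes", "esrd"):
        u = rng.random(n)
        p = np.array([spec.marginals[s].prevalences[flag] for s in sexes])
        flags[flag] = u < p

    t = spec.treatment_model
    logit = (
        t.intercept
        + t.age_coef * (cont["age"] - 60.0)
        + t.sbp_coef * (cont["sbp"] - 140.0)
    )
    p_treat = 1.0 / (1.0 + np.exp(-logit))
    on_treatment = rng.random(n) < p_treat

    sigma = spec.weight_model.sigma
    if sigma == 0:
        weights = np.ones(n)
    else:
        weights = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)

    out = []
    for i in range(n):
        out.append(
            Individual(
                id=f"P{i:06d}",
                age=int(cont["age"][i]),
                sex=str(sexes[i]),
                sbp=float(cont["sbp"][i]),
                dbp=float(cont["dbp"][i]),
                on_bp_treatment=bool(on_treatment[i]),
                smoker=bool(flags["smoker"][i]),
                total_chol=float(cont["total_chol"][i]),
                hdl_chol=float(cont["hdl_chol"][i]),
                hist_chd=bool(flags["hist_chd"][i]),
                hist_stroke=bool(flags["hist_stroke"][i]),
                hist_hf=bool(flags["hist_hf"][i]),
                diabetes=bool(flags["diabetes"][i]),
                esrd=bool(flags["esrd"][i]),
                survey_weight=float(weights[i]),
                creatinine=float(cont["creatinine"][i]),
            )
        )
    return out


class ReadResult(NamedTuple):
    individuals: list
    n_dropped_missing_sbp: int


def write_population(pop: Iterable[Individual], path) -> None:
    """Write a population to CSV (UTF-8, '.' decimal, documented columns)."""
    rows = []
    for ind in pop:
        row = {c: getattr(ind, c) for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
        for c in _FLAG_COLUMNS:
            row[c] = int(row[c])
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS + OPTIONAL_COLUMNS))
    df.to_csv(path, index=False, float_format="%.17g")


def _parse_optional_float(v):
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def read_population(path, dialect: Optional[dict] = None) -> ReadResult:
    """Read a population CSV; rows with missing SBP are dropped and counted.

    ``dialect`` maps our canonical column names to the file's column names.
    A missing required column raises FormatError; a non-numeric (but present)
    SBP raises RowError carrying the zero-based data-row index.
    """
    df = pd.read_csv(path, dtype={"id": str}, keep_default_na=True, float_precision="round_trip")
    if dialect:
        rename = {src: canon for canon, src in dialect.items()}
        df = df.rename(columns=rename)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"required column(s) missing: {missing_cols}")

    individuals: list[Individual] = []
    n_dropped = 0
    for i, row in enumerate(df.to_dict("records")):
        sbp_raw = row["sbp"]
        if sbp_raw is None or (isinstance(sbp_raw, float) and math.isnan(sbp_raw)) or sbp_raw == "":
            n_dropped += 1
            continue
        try:
            sbp = float(sbp_raw)
        except (TypeError, ValueError):
            raise RowError(i, f"non-numeric SBP value {sbp_raw!r}")
        n_med = row.get("n_bp_med_classes")
        if n_med is not None and not (isinstance(n_med, float) and math.isnan(n_med)):
            n_med = int(n_med)
        else:
            n_med = None
        ind = Individual(
            id=str(row["id"]),
            age=int(row["age"]),
            sex=str(row["sex"]),
            sbp=sbp,
            dbp=float(row["dbp"]),
            on_bp_treatment=bool(int(row["on_bp_treatment"])),
            smoker=bool(int(row["smoker"])),
            total_chol=float(row["total_chol"]),
            hdl_chol=float(row["hdl_chol"]),
            hist_chd=bool(int(row["hist_chd"])),
            hist_stroke=bool(int(row["hist_stroke"])),
            hist_hf=bool(int(row["hist_hf"])),
            diabetes=bool(int(row["diabetes"])),
            esrd=bool(int(row["esrd"])),
            survey_weight=float(row["survey_weight"]),
            n_bp_med_classes=n_med,
            egfr=_parse_optional_float(row.get("egfr")),
            creatinine=_parse_optional_float(row.get("creatinine")),
        )
        individuals.append(ind)
    return ReadResult(individuals, n_dropped)


class WeightedEstimate(NamedTuple):
    proportion: float
    se: float
    ci_low: float
    ci_high: float
    represented_count: float


def weighted_proportion(
    pop: Sequence[Individual], indicator: Callable[[Individual], bool]
) -> WeightedEstimate:
    """Survey-weighted proportion with a Wald CI.

    proportion = sum(w * 1[indicator]) / sum(w); the variance estimator is
    sum(w_i^2 (x_i - p)^2) / (sum w)^2 (no finite-population or
    stratification correction).
    """
    pop = list(pop)
    if not pop:
        raise EstimateError("cannot estimate a proportion on an empty population")
    w = np.array([ind.survey_weight for ind in pop], dtype=float)
    if (w <= 0).any():
        raise EstimateError("all survey weights must be positive")
    x = np.array([bool(indicator(ind)) for ind in pop], dtype=float)
    wsum = w.sum()
    p = float(np.dot(w, x) / wsum)
    var = float(np.sum(w**2 * (x - p) ** 2) / wsum**2)
    se = math.sqrt(var)
    ci_low = max(0.0, p - 1.959963984540054 * se)
    ci_high = min(1.0, p + 1.959963984540054 * se)
    return WeightedEstimate(p, se, ci_low, ci_high, float(np.dot(w, x)))


def spec_from_yaml(path) -> PopulationSpec:
    """Load a PopulationSpec from YAML (only scalar overrides supported)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    spec = PopulationSpec(
        n=int(raw.get("n", 1000)),
        seed=int(raw.get("seed", 0)),
        male_fraction=float(raw.get("male_fraction", 0.48)),
    )
    for sex in ("male", "female"):
        block = raw.get("marginals", {}).get(sex, {})
        m = spec.marginals[sex]
        m.means.update(block.get("means", {}))
        m.sds.update(block.get("sds", {}))
        m.prevalences.update(block.get("prevalences", {}))
    if "correlation" in raw:
        spec.correlation = np.asarray(raw["correlation"], dtype=float)
    tm = raw.get("treatment_model", {})
    spec.treatment_model = TreatmentModel(
        intercept=float(tm.get("intercept", -2.2)),
        age_coef=float(tm.get("age_coef", 0.03)),
        sbp_coef=float(tm.get("sbp_coef", 0.04)),
    )
    spec.weight_model = WeightModel(sigma=float(raw.get("weight_model", {}).get("sigma", 0.5)))
    return spec
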