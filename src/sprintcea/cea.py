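"""Cost-effectiveness analytics: ICER, national scaling, DSA, PSA, CEAC, subgroups."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .engine import Comparison, compare_strategies
from .errors import ConfigurationError, EstimateError
from .population import Individual
from .risk_models import ModelParams

__all__ = [
    "ICERResult",
    "ThresholdSpec",
    "PSASample",
    "TornadoRow",
    "CEAResult",
    "icer",
    "scale_to_population",
    "one_way_sensitivity",
    "psa",
    "ceac",
    "subgroup_analysis",
    "summarize_comparison",
]


@dataclass(frozen=True)
class ICERResult:
    """Quadrant-aware incremental cost-effectiveness ratio.

    ``label`` is one of 'icer' (NE quadrant ratio), 'dominant', 'dominated',
    'equivalent', 'undefined' (zero QALY difference with nonzero cost), or
    'icer_sw' (south-west quadrant ratio, reported with its quadrant tag).
    """

    label: str
    value: Optional[float]
    quadrant: str

    def __str__(self) -> str:
        if self.label in ("icer", "icer_sw"):
            return f"{self.value:,.0f} Int$/QALY ({self.quadrant})"
        return self.label


def icer(delta_cost: float, delta_qaly: float) -> ICERResult:
    if not (math.isfinite(delta_cost) and math.isfinite(delta_qaly)):
        raise ValueError("deltas must be finite")
    if delta_qaly == 0.0 and delta_cost == 0.0:
        return ICERResult("equivalent", None, "origin")
    if delta_qaly == 0.0:
        return ICERResult("undefined", None, "N" if delta_cost > 0 else "S")
    if delta_qaly > 0.0:
        if delta_cost <= 0.0:
            return ICERResult("dominant", None, "SE")
        return ICERResult("icer", delta_cost / delta_qaly, "NE")
    if delta_cost >= 0.0:
        return ICERResult("dominated", None, "NW")
    return ICERResult("icer_sw", delta_cost / delta_qaly, "SW")


@dataclass(frozen=True)
class ThresholdSpec:
    """Willingness-to-pay threshold with GDP-style multipliers."""

    wtp_per_qaly: float = 16782.0
    multipliers: tuple = (1.0, 2.0)

    def __post_init__(self):
        if self.wtp_per_qaly <= 0:
            raise ConfigurationError("willingness-to-pay must be positive")

    @property
    def thresholds(self) -> list[float]:
        return [self.wtp_per_qaly * m for m in self.multipliers]


def scale_to_population(rate_difference: float, eligible_millions: float) -> float:
    """Events (millions) = per-person rate difference x eligible population (millions)."""
    if eligible_millions <= 0:
        raise ValueError("eligible_millions must be positive")
    return rate_difference * eligible_millions


@dataclass(frozen=True)
class PSASample:
    draw_index: int
    parameters: dict
    d_cost: float
    d_qaly: float


@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    low: float
    high: float
    icer_low: ICERResult
    icer_high: ICERResult
    spread: float


def _icer_number(r: ICERResult) -> float:
    """Numeric stand-in for sorting/spread: dominant -> 0, dominated -> +inf-ish."""
    if r.label in ("icer", "icer_sw"):
        return float(r.value)
    if r.label == "dominant":
        return 0.0
    if r.label in ("dominated", "undefined"):
        return float("inf")
    return 0.0


def one_way_sensitivity(
    cohort: Sequence[Individual],
    params: ModelParams,
    seed,
    dsa_ranges: Optional[dict] = None,
) -> tuple[ICERResult, list[TornadoRow]]:
    """One-way DSA: re-run both arms at each range endpoint with the base seed.

    Common random numbers mean a zero-width range reproduces the base ICER
    exactly.  Rows come back sorted by |ICER_high - ICER_low| descending.
    """
    ranges = params.dsa_ranges if dsa_ranges is None else dsa_ranges
    base_comp = compare_strategies(cohort, params, seed)
    base_icer = icer(base_comp.mean_d_cost, base_comp.mean_d_qaly)
    rows = []
    for path, (lo, hi) in ranges.items():
        base_value = params.get_value(path)
        if not lo <= base_value <= hi:
            raise ConfigurationError(
                f"DSA range [{lo}, {hi}] for {path!r} excludes base value {base_value}"
            )
        results = {}
        for bound, value in (("low", lo), ("high", hi)):
            if value == base_value:
                results[bound] = base_icer
                continue
            comp = compare_strategies(cohort, params.with_value(path, value), seed)
            results[bound] = icer(comp.mean_d_cost, comp.mean_d_qaly)
        spread = abs(_icer_number(results["high"]) - _icer_number(results["low"]))
        rows.append(
            TornadoRow(
                parameter=path,
                low=lo,
                high=hi,
                icer_low=results["low"],
                icer_high=results["high"],
                spread=spread,
            )
        )
    rows.sort(key=lambda r: (-r.spread, r.parameter))
    return base_icer, rows


def _draw_parameter(rng: np.random.Generator, spec: dict) -> float:
    family = spec["family"]
    if family == "beta":
        return float(rng.beta(spec["a"], spec["b"]))
    if family == "gamma":
        return float(rng.gamma(spec["shape"], spec["scale"]))
    if family == "lognormal":
        return float(rng.lognormal(spec["mu"], spec["sigma"]))
    if family == "fixed":
        return float(spec["value"])
    raise ConfigurationError(f"unsupported PSA distribution family {family!r}")


def psa(
    cohort: Sequence[Individual],
    params: ModelParams,
    n_runs: int = 1000,
    seed: int = 0,
) -> list[PSASample]:
    """Probabilistic sensitivity analysis.

    Each run draws one value per configured distribution (independent draws),
    re-evaluates both arms by compare_strategies with a run-specific but
    seed-derived stream, and records the paired (d_cost, d_qaly).
    """
    if not params.psa_distributions:
        raise ConfigurationError("params.psa_distributions is empty")
    samples = []
    paths = sorted(params.psa_distributions)
    for r in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1000003, r]))
        drawn = {p: _draw_parameter(rng, params.psa_distributions[p]) for p in paths}
        run_params = params.with_values(drawn)
        comp = compare_strategies(cohort, run_params, (int(seed), 7919, r))
        samples.append(
            PSASample(
                draw_index=r,
                parameters=drawn,
                d_cost=comp.mean_d_cost,
                d_qaly=comp.mean_d_qaly,
            )
        )
    return samples


def ceac(samples: Sequence[PSASample], thresholds: Sequence[float]) -> dict:
    """P(cost-effective) at each threshold via the net-monetary-benefit rule:
    fraction of samples with lambda * dQALY - dCost > 0."""
    samples = list(samples)
    if not samples:
        raise EstimateError("CEAC needs at least one PSA sample")
    dc = np.array([s.d_cost for s in samples])
    dq = np.array([s.d_qaly for s in samples])
    return {
        float(lam): float(np.mean(lam * dq - dc > 0.0)) for lam in thresholds
    }


@dataclass
class CEAResult:
    """Table-style summary for one (sub)population."""

    label: str
    n_individuals: int
    mean_cost_intensive: float
    mean_cost_standard: float
    mean_qaly_intensive: float
    mean_qaly_standard: float
    d_cost: float
    d_qaly: float
    d_cost_interval: Optional[tuple] = None  # 2.5-97.5 PSA percentiles
    d_qaly_interval: Optional[tuple] = None
    icer: Optional[ICERResult] = None
    prob_cost_effective: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "n_individuals": self.n_individuals,
            "mean_cost_intensive": self.mean_cost_intensive,
            "mean_cost_standard": self.mean_cost_standard,
            "mean_qaly_intensive": self.mean_qaly_intensive,
            "mean_qaly_standard": self.mean_qaly_standard,
            "d_cost": self.d_cost,
            "d_qaly": self.d_qaly,
            "icer": str(self.icer) if self.icer else None,
            "prob_cost_effective": {str(k): v for k, v in self.prob_cost_effective.items()},
        }
        if self.d_cost_interval:
            d["d_cost_interval"] = list(self.d_cost_interval)
        if self.d_qaly_interval:
            d["d_qaly_interval"] = list(self.d_qaly_interval)
        return d


def summarize_comparison(
    label: str,
    comp: Comparison,
    samples: Optional[Sequence[PSASample]] = None,
    thresholds: Optional[ThresholdSpec] = None,
) -> CEAResult:
    """Fold a Comparison (plus optional PSA samples) into a CEAResult."""
    result = CEAResult(
        label=label,
        n_individuals=comp.intensive.n_individuals,
        mean_cost_intensive=comp.intensive.mean_cost,
        mean_cost_standard=comp.standard.mean_cost,
        mean_qaly_intensive=comp.intensive.mean_qaly,
        mean_qaly_standard=comp.standard.mean_qaly,
        d_cost=comp.mean_d_cost,
        d_qaly=comp.mean_d_qaly,
        icer=icer(comp.mean_d_cost, comp.mean_d_qaly),
    )
    if samples:
        dc = np.array([s.d_cost for s in samples])
        dq = np.array([s.d_qaly for s in samples])
        result.d_cost_interval = (
            float(np.percentile(dc, 2.5)),
            float(np.percentile(dc, 97.5)),
        )
        result.d_qaly_interval = (
            float(np.percentile(dq, 2.5)),
            float(np.percentile(dq, 97.5)),
        )
        spec = thresholds or ThresholdSpec()
        result.prob_cost_effective = ceac(samples, spec.thresholds)
    return result


def subgroup_analysis(
    pop: Sequence[Individual],
    params: ModelParams,
    subgroup_defs: dict,
    seed: int,
    n_boot: int = 1000,
    n_psa: int = 0,
    thresholds: Optional[ThresholdSpec] = None,
) -> dict:
    """Run bootstrap -> compare (-> PSA -> CEAC) within each subgroup.

    ``subgroup_defs`` maps label -> predicate on baseline covariates.  Each
    subgroup gets an independent seed derived from the master seed.  Empty
    subgroups are skipped with a warning.
    """
    from .engine import bootstrap_individuals

    out = {}
    for k, (label, predicate) in enumerate(sorted(subgroup_defs.items())):
        members = [ind for ind in pop if predicate(ind)]
        if not members:
            warnings.warn(f"subgroup {label!r} is empty; skipped", RuntimeWarning)
            out[label] = None
            continue
        cohort = bootstrap_individuals(members, n_boot, (seed, 31, k))
        comp = compare_strategies(cohort, params, (seed, 37, k))
        samples = psa(cohort, params, n_psa, seed=seed * 1009 + k) if n_psa else None
        out[label] = summarize_comparison(label, comp, samples, thresholds)
    return out
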