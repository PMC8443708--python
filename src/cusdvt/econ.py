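"""Decision-tree cost-effectiveness model for DVT diagnostic pathways.

Diagnostic strategies are rooted decision trees whose internal nodes are
tests (Wells score, D-dimer, specialist proximal ultrasound, ML-guided
compression exam) and whose leaves are ``treat`` / ``no_treat`` decisions.
A cohort is split into patients with and without proximal DVT at a given
prevalence; exact enumeration over test-result paths (no simulation)
yields the four diagnostic-accuracy outcome likelihoods (TP, FP, TN, FN)
and per-test usage fractions.  Outcome payoffs (lifetime discounted QALYs
and costs) turn these into expected costs and QALYs per patient, from
which net monetary benefit at a willingness-to-pay λ

    NMB(c) = λ·ΔQALY + (cost_without − cost_with(c))

and ICERs are computed; ``c`` is the price charged per software-guided
examination, entering once per exam that uses the ML test.

Parameter uncertainty is propagated by probabilistic sensitivity analysis:
every parameter carries a distribution (beta, gamma, Dirichlet or fixed)
mirroring the published tables, with analytic means cross-checked against
the printed point estimates at load time; the handful of internally
inconsistent published rows are flagged rather than silently used.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Any, Iterable, Mapping

import numpy as np

__all__ = [
    "DistributionSpec",
    "DirichletSpec",
    "TestSpec",
    "PathwaySpec",
    "OutcomePayoff",
    "EconConfig",
    "EconResult",
    "EconParams",
    "InconsistentParameterWarning",
    "load_params",
    "outcome_likelihoods",
    "expected_outcomes",
    "evaluate_pathway",
    "nmb",
    "nmb_curve",
    "icer",
    "derive_payoffs",
    "derive_all_payoffs",
    "build_pathway_preset",
    "sample_psa",
]

OUTCOMES = ("tp", "fp", "tn", "fn")


class InconsistentParameterWarning(UserWarning):
    """A published distribution's analytic mean disagrees with its printed mean."""


# ---------------------------------------------------------------------------
# Parameter distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """A scalar parameter with its stochastic encoding and printed mean."""

    name: str
    family: str                      # beta | gamma | fixed
    params: Mapping[str, float]
    printed_mean: float | None = None
    note: str | None = None

    def analytic_mean(self) -> float:
        if self.family == "beta":
            a, b = self.params["a"], self.params["b"]
            return a / (a + b)
        if self.family == "gamma":
            return self.params["shape"] * self.params["scale"]
        if self.family == "fixed":
            return float(self.params["value"])
        raise ValueError(f"unknown distribution family {self.family!r}")

    @property
    def flagged(self) -> bool:
        """True when the analytic and printed means disagree beyond tolerance."""
        if self.printed_mean is None or self.family == "fixed":
            return False
        tol = max(0.005, 0.005 * abs(self.printed_mean))
        return abs(self.analytic_mean() - self.printed_mean) > tol

    def mean(self) -> float:
        """Deterministic value: the printed mean when given, else the analytic one."""
        return self.printed_mean if self.printed_mean is not None else self.analytic_mean()

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "beta":
            return rng.beta(self.params["a"], self.params["b"], size=n)
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size=n)
        if self.family == "fixed":
            return np.full(n, float(self.params["value"]))
        raise ValueError(f"unknown distribution family {self.family!r}")


@dataclass(frozen=True)
class DirichletSpec:
    """A categorical split encoded as Dirichlet concentration counts."""

    name: str
    categories: tuple[str, ...]
    counts: tuple[float, ...]
    printed_means: tuple[float, ...] | None = None
    note: str | None = None
    fixed: bool = False          # degenerate mode: sampling returns the mean

    def analytic_mean(self) -> np.ndarray:
        c = np.asarray(self.counts, dtype=float)
        return c / c.sum()

    @property
    def flagged(self) -> bool:
        if self.printed_means is None:
            return False
        return bool(np.any(np.abs(self.analytic_mean() - np.asarray(self.printed_means)) > 0.005))

    def mean(self) -> dict[str, float]:
        """Deterministic split: count-implied means (always internally consistent)."""
        return dict(zip(self.categories, self.analytic_mean()))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.fixed:
            return np.tile(self.analytic_mean(), (n, 1))
        return rng.dirichlet(np.asarray(self.counts, dtype=float), size=n)


def _dist(name: str, d: Mapping[str, Any]) -> DistributionSpec:
    return DistributionSpec(name=name, family=d["family"], params=dict(d["params"]),
                            printed_mean=d.get("printed_mean"), note=d.get("note"))


def _dirichlet(name: str, d: Mapping[str, Any]) -> DirichletSpec:
    return DirichletSpec(name=name, categories=tuple(d["categories"]),
                         counts=tuple(d["params"]["counts"]),
                         printed_means=tuple(d["printed_means"]) if d.get("printed_means") else None,
                         note=d.get("note"))


@dataclass(frozen=True)
class EconParams:
    """The full published parameter set, with flagged-inconsistency bookkeeping."""

    prevalence: DistributionSpec
    wells_cost: DistributionSpec
    wells_dvt_split: DirichletSpec
    wells_no_dvt_split: DirichletSpec
    ddimer_cost: DistributionSpec
    ddimer_sensitivity: DistributionSpec
    ddimer_specificity_by_wells: Mapping[str, DistributionSpec]
    us_cost: DistributionSpec
    us_sensitivity: DistributionSpec
    us_specificity: DistributionSpec
    treated_fatal_pe: DistributionSpec
    treated_nonfatal_pe: DistributionSpec
    treated_pts: DistributionSpec
    warfarin_split: DirichletSpec
    untreated_fatal_pe: DistributionSpec
    untreated_nonfatal_pe: DistributionSpec
    untreated_pts: DistributionSpec
    base_qale: DistributionSpec
    utility_nonfatal_pe: DistributionSpec
    utility_intracranial: DistributionSpec
    utility_pts: DistributionSpec
    event_costs: Mapping[str, float]
    treatment_cost: float
    payoffs: "OutcomePayoff | None"
    table6_rows: Mapping[str, Mapping[str, float]]

    def all_specs(self) -> list[DistributionSpec | DirichletSpec]:
        out: list[DistributionSpec | DirichletSpec] = [
            self.prevalence, self.wells_cost, self.wells_dvt_split,
            self.wells_no_dvt_split, self.ddimer_cost, self.ddimer_sensitivity,
            *self.ddimer_specificity_by_wells.values(), self.us_cost,
            self.us_sensitivity, self.us_specificity, self.treated_fatal_pe,
            self.treated_nonfatal_pe, self.treated_pts, self.warfarin_split,
            self.untreated_fatal_pe, self.untreated_nonfatal_pe,
            self.untreated_pts, self.base_qale, self.utility_nonfatal_pe,
            self.utility_intracranial, self.utility_pts,
        ]
        return out

    def flagged_specs(self) -> list[str]:
        return [s.name for s in self.all_specs() if s.flagged]


def load_params(path: str | None = None, warn: bool = True) -> EconParams:
    """Load the published parameter tables (or a user-supplied JSON mirror).

    Emits an :class:`InconsistentParameterWarning` naming every parameter
    whose analytic mean disagrees with its printed mean.
    """
    if path is None:
        raw = json.loads(
            resources.files("cusdvt.data").joinpath("econ_params.json").read_text()
        )
    else:
        with open(path) as fh:
            raw = json.load(fh)

    table14 = raw.get("payoffs")
    payoffs = OutcomePayoff.from_table(table14) if table14 else None
    p = EconParams(
        prevalence=_dist("prevalence", raw["prevalence"]),
        wells_cost=_dist("wells_cost", raw["wells"]["cost"]),
        wells_dvt_split=_dirichlet("wells_dvt_split", raw["wells"]["dvt_split"]),
        wells_no_dvt_split=_dirichlet("wells_no_dvt_split", raw["wells"]["no_dvt_split"]),
        ddimer_cost=_dist("ddimer_cost", raw["d_dimer"]["cost"]),
        ddimer_sensitivity=_dist("ddimer_sensitivity", raw["d_dimer"]["sensitivity"]),
        ddimer_specificity_by_wells={
            k: _dist(f"ddimer_specificity_{k}", v)
            for k, v in raw["d_dimer"]["specificity_by_wells"].items()
        },
        us_cost=_dist("us_cost", raw["ultrasound"]["cost"]),
        us_sensitivity=_dist("us_sensitivity", raw["ultrasound"]["sensitivity"]),
        us_specificity=_dist("us_specificity", raw["ultrasound"]["specificity"]),
        treated_fatal_pe=_dist("treated_fatal_pe", raw["treated_dvt"]["fatal_pe"]),
        treated_nonfatal_pe=_dist("treated_nonfatal_pe", raw["treated_dvt"]["nonfatal_pe"]),
        treated_pts=_dist("treated_pts", raw["treated_dvt"]["pts"]),
        warfarin_split=_dirichlet("warfarin_split", raw["treated_dvt"]["warfarin_split"]),
        untreated_fatal_pe=_dist("untreated_fatal_pe", raw["untreated_dvt"]["fatal_pe"]),
        untreated_nonfatal_pe=_dist("untreated_nonfatal_pe", raw["untreated_dvt"]["nonfatal_pe"]),
        untreated_pts=_dist("untreated_pts", raw["untreated_dvt"]["pts"]),
        base_qale=_dist("base_qale", raw["utilities"]["base_qale"]),
        utility_nonfatal_pe=_dist("utility_nonfatal_pe", raw["utilities"]["nonfatal_pe"]),
        utility_intracranial=_dist(
            "utility_intracranial", raw["utilities"]["nonfatal_intracranial_haemorrhage"]
        ),
        utility_pts=_dist("utility_pts", raw["utilities"]["pts"]),
        event_costs=dict(raw["event_costs"]),
        treatment_cost=float(raw["treatment_cost"]),
        payoffs=payoffs,
        table6_rows={k: dict(v) for k, v in raw.get("table6_rows", {}).items()},
    )
    if warn:
        for name in p.flagged_specs():
            warnings.warn(
                f"published parameter {name!r}: analytic mean disagrees with the "
                f"printed mean; printed value used deterministically",
                InconsistentParameterWarning,
                stacklevel=2,
            )
    return p


# ---------------------------------------------------------------------------
# Tests and pathways
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestSpec:
    """A diagnostic test: cost per administration plus its error model.

    Binary tests carry (sensitivity, specificity); the specificity may be a
    mapping keyed by Wells category (the D-dimer case), resolved from the
    Wells result earlier on the same path, with a ``default`` key for
    pathways that run the test without a preceding Wells score.
    Categorical tests (the Wells score itself) carry result splits
    conditional on DVT status.
    """

    name: str
    cost: float
    sensitivity: float | None = None
    specificity: "float | Mapping[str, float] | None" = None
    split_dvt: Mapping[str, float] | None = None       # categorical only
    split_no_dvt: Mapping[str, float] | None = None

    @property
    def categorical(self) -> bool:
        return self.split_dvt is not None

    def __post_init__(self) -> None:
        if self.categorical:
            for split in (self.split_dvt, self.split_no_dvt):
                if split is None or abs(sum(split.values()) - 1.0) > 1e-9:
                    raise ValueError(f"test {self.name!r}: categorical split must sum to 1")
        else:
            if self.sensitivity is None or self.specificity is None:
                raise ValueError(f"test {self.name!r}: binary test needs sensitivity and specificity")

    def result_probs(self, has_dvt: bool, wells_category: str | None) -> dict[str, float]:
        if self.categorical:
            split = self.split_dvt if has_dvt else self.split_no_dvt
            return dict(split)  # type: ignore[arg-type]
        if has_dvt:
            s = self.sensitivity
            return {"positive": s, "negative": 1 - s}
        sp = self.specificity
        if isinstance(sp, Mapping):
            key = wells_category if wells_category in sp else "default"
            if key not in sp:
                raise ValueError(
                    f"test {self.name!r}: no specificity for Wells category "
                    f"{wells_category!r} and no default"
                )
            sp = sp[key]
        return {"positive": 1 - sp, "negative": sp}


@dataclass(frozen=True)
class PathwaySpec:
    """A rooted decision tree over tests, serializable to/from plain JSON.

    ``root`` is a nested dict: internal nodes are
    ``{"test": <name>, "children": {result: node, ...}}`` and leaves are
    ``{"leaf": "treat" | "no_treat"}``.
    """

    variant: str
    description: str
    root: Mapping[str, Any]

    def validate(self, tests: Mapping[str, TestSpec]) -> None:
        def walk(node: Mapping[str, Any]) -> None:
            if "leaf" in node:
                if node["leaf"] not in ("treat", "no_treat"):
                    raise ValueError(f"invalid leaf {node['leaf']!r}")
                return
            if "test" not in node or "children" not in node:
                raise ValueError(f"malformed pathway node: {node!r}")
            name = node["test"]
            if name not in tests:
                raise ValueError(f"pathway references unknown test {name!r}")
            spec = tests[name]
            expected = (set(spec.split_dvt) if spec.categorical
                        else {"positive", "negative"})
            got = set(node["children"])
            if got != expected:
                raise ValueError(
                    f"node for test {name!r}: result map {sorted(got)} does not "
                    f"match the test's result set {sorted(expected)}"
                )
            for child in node["children"].values():
                walk(child)

        walk(self.root)

    def to_json(self) -> str:
        return json.dumps(
            {"variant": self.variant, "description": self.description, "root": self.root},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PathwaySpec":
        d = json.loads(text)
        return cls(variant=d["variant"], description=d["description"], root=d["root"])


@dataclass(frozen=True)
class OutcomePayoff:
    """Lifetime discounted QALYs and cost per diagnostic-accuracy outcome."""

    qalys: Mapping[str, float]
    costs: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [o for o in OUTCOMES if o not in self.qalys or o not in self.costs]
        if missing:
            raise ValueError(f"payoffs missing outcomes: {missing}")
        if any(q < 0 for q in self.qalys.values()):
            raise ValueError("QALYs must be non-negative")

    @classmethod
    def from_table(cls, rows: Mapping[str, Mapping[str, float]]) -> "OutcomePayoff":
        return cls({o: rows[o]["qalys"] for o in OUTCOMES},
                   {o: rows[o]["cost"] for o in OUTCOMES})


@dataclass(frozen=True)
class EconConfig:
    prevalence: float = 0.147
    willingness_to_pay: float = 20_000.0
    software_cost_per_exam: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.willingness_to_pay <= 0:
            raise ValueError("willingness to pay must be > 0")
        if self.software_cost_per_exam < 0:
            raise ValueError("software cost must be >= 0")


@dataclass(frozen=True)
class EconResult:
    """Expected per-patient outcome of one pathway at one parameter set."""

    likelihoods: Mapping[str, float]
    usage: Mapping[str, float]
    expected_qalys: float
    expected_cost: float          # includes software cost at config's price
    base_cost: float              # cost with software price c = 0
    software_usage: float         # fraction of patients receiving the ML exam
    prevalence: float

    def __post_init__(self) -> None:
        total = sum(self.likelihoods.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"outcome likelihoods sum to {total}, not 1")
        tp_fn = self.likelihoods["tp"] + self.likelihoods["fn"]
        if abs(tp_fn - self.prevalence) > 1e-9:
            raise ValueError("TP + FN must equal prevalence")

    def cost_at(self, software_cost: float) -> float:
        return self.base_cost + software_cost * self.software_usage


# ---------------------------------------------------------------------------
# Enumeration and expectation
# ---------------------------------------------------------------------------

def outcome_likelihoods(
    pathway: PathwaySpec,
    prevalence: float,
    tests: Mapping[str, TestSpec],
) -> tuple[dict[str, float], dict[str, float]]:
    """Exact outcome likelihoods and per-test usage fractions for a pathway.

    Enumerates every root-to-leaf path for both DVT states, assuming test
    errors conditionally independent given DVT status except the D-dimer
    specificity, which is conditioned on the Wells category observed
    earlier on the same path.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    pathway.validate(tests)

    lik = {o: 0.0 for o in OUTCOMES}
    usage: dict[str, float] = {name: 0.0 for name in tests}

    def walk(node: Mapping[str, Any], p_dvt: float, p_no: float,
             wells_cat: str | None) -> None:
        if "leaf" in node:
            treat = node["leaf"] == "treat"
            if treat:
                lik["tp"] += prevalence * p_dvt
                lik["fp"] += (1 - prevalence) * p_no
            else:
                lik["fn"] += prevalence * p_dvt
                lik["tn"] += (1 - prevalence) * p_no
            return
        spec = tests[node["test"]]
        usage[spec.name] += prevalence * p_dvt + (1 - prevalence) * p_no
        probs_dvt = spec.result_probs(True, wells_cat)
        probs_no = spec.result_probs(False, wells_cat)
        for result, child in node["children"].items():
            cat = result if spec.categorical else wells_cat
            walk(child, p_dvt * probs_dvt[result], p_no * probs_no[result], cat)

    walk(pathway.root, 1.0, 1.0, None)
    return lik, usage


def expected_outcomes(
    likelihoods: Mapping[str, float],
    usage: Mapping[str, float],
    payoffs: OutcomePayoff,
    test_costs: Mapping[str, float],
    config: EconConfig,
    software_test: str = "ml_exam",
) -> EconResult:
    """Combine outcome likelihoods and test usage into expected cost / QALYs.

    Expected QALYs = Σ likelihood·payoff_qalys.  Expected cost adds outcome
    costs, per-test administration costs weighted by usage, and the software
    price once per ML-guided exam.
    """
    if any(c < 0 for c in test_costs.values()):
        raise ValueError("test costs must be non-negative")
    eq = sum(likelihoods[o] * payoffs.qalys[o] for o in OUTCOMES)
    base = sum(likelihoods[o] * payoffs.costs[o] for o in OUTCOMES)
    base += sum(usage.get(name, 0.0) * cost for name, cost in test_costs.items())
    sw_usage = usage.get(software_test, 0.0)
    return EconResult(
        likelihoods=dict(likelihoods),
        usage=dict(usage),
        expected_qalys=eq,
        expected_cost=base + config.software_cost_per_exam * sw_usage,
        base_cost=base,
        software_usage=sw_usage,
        prevalence=likelihoods["tp"] + likelihoods["fn"],
    )


def evaluate_pathway(
    pathway: PathwaySpec,
    tests: Mapping[str, TestSpec],
    payoffs: OutcomePayoff,
    config: EconConfig,
) -> EconResult:
    """Enumerate a pathway and apply payoffs in one step (deterministic run)."""
    lik, usage = outcome_likelihoods(pathway, config.prevalence, tests)
    test_costs = {name: t.cost for name, t in tests.items()}
    return expected_outcomes(lik, usage, payoffs, test_costs, config)


# ---------------------------------------------------------------------------
# NMB / ICER
# ---------------------------------------------------------------------------

def nmb(
    result_with: EconResult,
    result_without: EconResult,
    willingness_to_pay: float,
    software_cost: float = 0.0,
) -> float:
    """Net monetary benefit per examination of the software-supported pathway.

    NMB(c) = λ·(QALY_with − QALY_without) + (cost_without − cost_with(c));
    affine in c with slope −(software exam usage fraction).
    """
    if abs(result_with.prevalence - result_without.prevalence) > 1e-9:
        raise ValueError("results come from different prevalences")
    dq = result_with.expected_qalys - result_without.expected_qalys
    dc = result_without.base_cost - result_with.cost_at(software_cost)
    return willingness_to_pay * dq + dc


def nmb_curve(
    pathways: Mapping[str, EconResult],
    baseline: EconResult,
    willingness_to_pay: float,
    cost_grid: Iterable[float],
) -> dict[str, dict[str, Any]]:
    """NMB(c) along a software-cost grid per variant, with break-even costs.

    Returns ``{variant: {"cost": grid, "nmb": values, "break_even": c*}}``
    where ``c*`` is the software cost at which NMB crosses zero (linear
    interpolation; None when NMB(0) ≤ 0 or the slope is zero).
    """
    grid = np.asarray(list(cost_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("cost grid must be non-empty")
    if np.any(np.diff(grid) < 0) or np.any(grid < 0):
        raise ValueError("cost grid must be non-negative and ascending")
    out: dict[str, dict[str, Any]] = {}
    for name, result in pathways.items():
        values = np.array([nmb(result, baseline, willingness_to_pay, c) for c in grid])
        at_zero = nmb(result, baseline, willingness_to_pay, 0.0)
        slope = -result.software_usage
        if at_zero > 0 and slope < 0:
            break_even = at_zero / result.software_usage
        else:
            break_even = None
        out[name] = {"cost": grid, "nmb": values, "break_even": break_even}
    return out


def icer(result_a: EconResult, result_b: EconResult) -> dict[str, Any]:
    """Incremental cost-effectiveness ratio of A vs B, with dominance flags."""
    d_cost = result_a.expected_cost - result_b.expected_cost
    d_qaly = result_a.expected_qalys - result_b.expected_qalys
    out: dict[str, Any] = {"delta_cost": d_cost, "delta_qalys": d_qaly,
                           "ratio": None, "flag": None}
    if abs(d_qaly) < 1e-9:
        out["flag"] = "cost_minimisation" if d_cost >= 0 else "cost_saving"
        return out
    if d_cost <= 0 and d_qaly > 0:
        out["flag"] = "dominant"
        return out
    if d_cost >= 0 and d_qaly < 0:
        out["flag"] = "dominated"
        return out
    out["ratio"] = d_cost / d_qaly
    return out


# ---------------------------------------------------------------------------
# Payoff derivation from event probabilities
# ---------------------------------------------------------------------------

def derive_payoffs(
    fatal_events: Mapping[str, float],
    nonfatal_events: Mapping[str, tuple[float, float]],
    base_qale: float,
    event_costs: Mapping[str, float],
    treated: bool,
    treatment_cost: float = 0.0,
) -> tuple[float, float]:
    """(QALYs, cost) for one diagnostic-accuracy outcome.

    ``fatal_events`` maps event → probability (QALY contribution is a full
    loss of the remaining QALE); ``nonfatal_events`` maps event →
    (probability, lifetime utility multiplier).  Events combine additively,
    i.e. as approximately mutually exclusive:

        QALYs = base_qale · (1 − Σ p_fatal − Σ p_nonfatal·(1 − multiplier))
        cost  = Σ p_event·event_cost (+ treatment cost when treated)
    """
    probs = list(fatal_events.values()) + [p for p, _ in nonfatal_events.values()]
    if any(not 0 <= p <= 1 for p in probs):
        raise ValueError("event probabilities must be in [0, 1]")
    if any(not 0 <= m <= 1 for _, m in nonfatal_events.values()):
        raise ValueError("utility multipliers must be in [0, 1]")
    loss = sum(fatal_events.values())
    loss += sum(p * (1 - m) for p, m in nonfatal_events.values())
    if loss > 1:
        raise ValueError("combined event probability mass exceeds 1")
    qalys = base_qale * (1 - loss)
    cost = sum(
        p * event_costs.get(name, 0.0)
        for name, p in {**fatal_events,
                        **{k: v[0] for k, v in nonfatal_events.items()}}.items()
    )
    if treated:
        cost += treatment_cost
    return qalys, cost


def derive_all_payoffs(params: EconParams, values: Mapping[str, float] | None = None) -> OutcomePayoff:
    """Recompute the four outcome payoffs from event-level parameters.

    ``values`` may override individual parameter values (used by the PSA);
    otherwise deterministic means are used.  Haemorrhage splits always use
    count-implied means so the four components stay a proper distribution.
    """
    v: dict[str, float] = {}
    v["base_qale"] = params.base_qale.mean()
    v["u_pe"] = params.utility_nonfatal_pe.mean()
    v["u_ich"] = params.utility_intracranial.mean()
    v["u_pts"] = params.utility_pts.mean()
    for name in ("treated_fatal_pe", "treated_nonfatal_pe", "treated_pts",
                 "untreated_fatal_pe", "untreated_nonfatal_pe", "untreated_pts"):
        spec: DistributionSpec = getattr(params, name)
        v[name] = spec.mean()
    warf = params.warfarin_split.mean()
    v.update({f"warfarin_{k}": p for k, p in warf.items()})
    if values:
        v.update(values)

    ec = params.event_costs
    haem_fatal = {"fatal_haemorrhage": v["warfarin_fatal_haemorrhage"]}
    haem_nonfatal = {
        "nonfatal_intracranial_haemorrhage":
            (v["warfarin_nonfatal_intracranial_haemorrhage"], v["u_ich"]),
        # no published utility decrement for non-intracranial bleeds: cost only
        "nonfatal_nonintracranial_haemorrhage":
            (v["warfarin_nonfatal_nonintracranial_haemorrhage"], 1.0),
    }
    tp_q, tp_c = derive_payoffs(
        fatal_events={"fatal_pe": v["treated_fatal_pe"], **haem_fatal},
        nonfatal_events={"nonfatal_pe": (v["treated_nonfatal_pe"], v["u_pe"]),
                         "pts": (v["treated_pts"], v["u_pts"]),
                         **haem_nonfatal},
        base_qale=v["base_qale"], event_costs=ec, treated=True,
        treatment_cost=params.treatment_cost,
    )
    fn_q, fn_c = derive_payoffs(
        fatal_events={"fatal_pe": v["untreated_fatal_pe"]},
        nonfatal_events={"nonfatal_pe": (v["untreated_nonfatal_pe"], v["u_pe"]),
                         "pts": (v["untreated_pts"], v["u_pts"])},
        base_qale=v["base_qale"], event_costs=ec, treated=False,
    )
    fp_q, fp_c = derive_payoffs(
        fatal_events=haem_fatal,
        nonfatal_events=haem_nonfatal,
        base_qale=v["base_qale"], event_costs=ec, treated=True,
        treatment_cost=params.treatment_cost,
    )
    tn_q, tn_c = derive_payoffs(
        fatal_events={}, nonfatal_events={},
        base_qale=v["base_qale"], event_costs=ec, treated=False,
    )
    return OutcomePayoff(
        qalys={"tp": tp_q, "fn": fn_q, "fp": fp_q, "tn": tn_q},
        costs={"tp": tp_c, "fn": fn_c, "fp": fp_c, "tn": tn_c},
    )


# ---------------------------------------------------------------------------
# Pathway presets
# ---------------------------------------------------------------------------

def default_tests(
    params: EconParams,
    ml_sensitivity: float | None = None,
    ml_specificity: float | None = None,
    ml_cost: float = 0.0,
) -> dict[str, TestSpec]:
    """Instantiate the standard tests at the deterministic parameter means.

    The ML exam is included only when its sensitivity/specificity are given;
    its administration cost excludes the software price, which is accounted
    separately so NMB-vs-price curves stay affine.
    """
    tests = {
        "wells": TestSpec(
            name="wells", cost=params.wells_cost.mean(),
            split_dvt=params.wells_dvt_split.mean(),
            split_no_dvt=params.wells_no_dvt_split.mean(),
        ),
        "d_dimer": TestSpec(
            name="d_dimer", cost=params.ddimer_cost.mean(),
            sensitivity=params.ddimer_sensitivity.mean(),
            specificity={
                **{k: s.mean() for k, s in params.ddimer_specificity_by_wells.items()},
                "default": params.ddimer_specificity_by_wells["moderate"].mean(),
            },
        ),
        "ultrasound": TestSpec(
            name="ultrasound", cost=params.us_cost.mean(),
            sensitivity=params.us_sensitivity.mean(),
            specificity=params.us_specificity.mean(),
        ),
    }
    if ml_sensitivity is not None:
        if ml_specificity is None:
            raise ValueError("ml_specificity required when ml_sensitivity is given")
        tests["ml_exam"] = TestSpec(
            name="ml_exam", cost=ml_cost,
            sensitivity=ml_sensitivity, specificity=ml_specificity,
        )
    return tests


def _leaf(kind: str) -> dict[str, str]:
    return {"leaf": kind}


def _us_node() -> dict[str, Any]:
    return {"test": "ultrasound",
            "children": {"positive": _leaf("treat"), "negative": _leaf("no_treat")}}


def _ml_then_us() -> dict[str, Any]:
    return {"test": "ml_exam",
            "children": {"positive": _us_node(), "negative": _leaf("no_treat")}}


def build_pathway_preset(variant: str) -> PathwaySpec:
    """Documented, editable approximations of the integration strategies a-f.

    (a) is the current UK clinical algorithm (Wells, then D-dimer for
    non-high-risk patients, with specialist ultrasound confirming positives).
    (b)-(d) insert the ML-guided exam as a rule-out / triage step before
    specialist ultrasound at different points; (e)-(f) use it in more
    ultrasound-intensive roles (standalone, or with an ultrasound backstop
    for ML-negative patients).  The published figures do not print the full
    branch structure, so these trees are explicit and serializable rather
    than claimed faithful.
    """
    ddimer_then_us = {
        "test": "d_dimer",
        "children": {"positive": _us_node(), "negative": _leaf("no_treat")},
    }
    if variant == "a":
        return PathwaySpec(
            variant="a",
            description="Current pathway: Wells; high risk straight to ultrasound, "
                        "otherwise D-dimer gates ultrasound.",
            root={"test": "wells",
                  "children": {"high": _us_node(),
                               "moderate": ddimer_then_us,
                               "low": json.loads(json.dumps(ddimer_then_us))}},
        )
    if variant == "b":
        return PathwaySpec(
            variant="b",
            description="ML exam as first-line rule-out; positives confirmed by "
                        "specialist ultrasound.",
            root=_ml_then_us(),
        )
    if variant == "c":
        return PathwaySpec(
            variant="c",
            description="Current pathway with the ML exam triaging every "
                        "ultrasound referral.",
            root={"test": "wells",
                  "children": {"high": _ml_then_us(),
                               "moderate": {"test": "d_dimer",
                                            "children": {"positive": _ml_then_us(),
                                                         "negative": _leaf("no_treat")}},
                               "low": {"test": "d_dimer",
                                       "children": {"positive": _ml_then_us(),
                                                    "negative": _leaf("no_treat")}}}},
        )
    if variant == "d":
        return PathwaySpec(
            variant="d",
            description="D-dimer first for everyone; positives triaged by the ML "
                        "exam before specialist ultrasound.",
            root={"test": "d_dimer",
                  "children": {"positive": _ml_then_us(),
                               "negative": _leaf("no_treat")}},
        )
    if variant == "e":
        return PathwaySpec(
            variant="e",
            description="Standalone ML exam: positives treated without "
                        "confirmatory ultrasound.",
            root={"test": "ml_exam",
                  "children": {"positive": _leaf("treat"),
                               "negative": _leaf("no_treat")}},
        )
    if variant == "f":
        return PathwaySpec(
            variant="f",
            description="ML exam first; positives treated directly, negatives "
                        "receive a specialist ultrasound backstop.",
            root={"test": "ml_exam",
                  "children": {"positive": _leaf("treat"),
                               "negative": _us_node()}},
        )
    raise ValueError(f"unknown pathway variant {variant!r}")


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def sample_psa(
    params: EconParams,
    pathway_with: PathwaySpec,
    pathway_without: PathwaySpec,
    ml_sensitivity: float,
    ml_specificity: float,
    n_draws: int,
    seed: int,
    config: EconConfig | None = None,
    use_printed_payoffs: bool = False,
) -> dict[str, Any]:
    """Monte-Carlo parameter uncertainty propagated through both pathways.

    Each draw samples every non-fixed distribution independently, re-derives
    outcome payoffs from the drawn event probabilities and utilities (unless
    ``use_printed_payoffs``), evaluates both pathways deterministically at
    the drawn values, and records cost, QALYs and NMB at the configured
    willingness-to-pay and software price.  Returns per-draw arrays plus a
    summary (means, 2.5%/97.5% quantiles, P(NMB > 0)).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    cfg = config or EconConfig()
    rng = np.random.default_rng(seed)

    prev = params.prevalence.sample(rng, n_draws)
    dd_sens = params.ddimer_sensitivity.sample(rng, n_draws)
    dd_spec = {k: s.sample(rng, n_draws)
               for k, s in params.ddimer_specificity_by_wells.items()}
    wells_dvt = params.wells_dvt_split.sample(rng, n_draws)
    wells_no = params.wells_no_dvt_split.sample(rng, n_draws)
    costs = {name: getattr(params, name).sample(rng, n_draws)
             for name in ("wells_cost", "ddimer_cost", "us_cost")}
    event_draws = {
        name: getattr(params, name).sample(rng, n_draws)
        for name in ("treated_nonfatal_pe", "treated_pts",
                     "untreated_fatal_pe", "untreated_nonfatal_pe", "untreated_pts")
    }
    # treated fatal PE: printed mean 0 conflicts with its beta parameters;
    # the deterministic zero is kept in PSA as well (the flag records the clash)
    event_draws["treated_fatal_pe"] = np.zeros(n_draws)
    warf = params.warfarin_split.sample(rng, n_draws)
    utils = {
        "u_pe": params.utility_nonfatal_pe.sample(rng, n_draws),
        "u_ich": params.utility_intracranial.sample(rng, n_draws),
        "u_pts": params.utility_pts.sample(rng, n_draws),
    }

    cats = params.wells_dvt_split.categories
    wcats = params.warfarin_split.categories
    cost_w, cost_q, nmb_vals = (np.empty(n_draws) for _ in range(3))
    cost_wo, qaly_wo = np.empty(n_draws), np.empty(n_draws)
    printed = params.payoffs
    for i in range(n_draws):
        tests = {
            "wells": TestSpec(
                name="wells", cost=costs["wells_cost"][i],
                split_dvt=dict(zip(cats, wells_dvt[i])),
                split_no_dvt=dict(zip(cats, wells_no[i])),
            ),
            "d_dimer": TestSpec(
                name="d_dimer", cost=costs["ddimer_cost"][i],
                sensitivity=dd_sens[i],
                specificity={**{k: dd_spec[k][i] for k in dd_spec},
                             "default": dd_spec["moderate"][i]},
            ),
            "ultrasound": TestSpec(
                name="ultrasound", cost=costs["us_cost"][i],
                sensitivity=params.us_sensitivity.mean(),
                specificity=params.us_specificity.mean(),
            ),
            "ml_exam": TestSpec(
                name="ml_exam", cost=0.0,
                sensitivity=ml_sensitivity, specificity=ml_specificity,
            ),
        }
        if use_printed_payoffs and printed is not None:
            payoffs = printed
        else:
            overrides = {**event_draws, **utils}
            overrides = {k: v[i] for k, v in overrides.items()}
            overrides.update({f"warfarin_{k}": warf[i][j] for j, k in enumerate(wcats)})
            payoffs = derive_all_payoffs(params, overrides)
        cfg_i = replace(cfg, prevalence=float(prev[i]))
        r_with = evaluate_pathway(pathway_with, tests, payoffs, cfg_i)
        r_wo = evaluate_pathway(pathway_without, tests, payoffs, cfg_i)
        cost_w[i] = r_with.expected_cost
        cost_q[i] = r_with.expected_qalys
        cost_wo[i] = r_wo.expected_cost
        qaly_wo[i] = r_wo.expected_qalys
        nmb_vals[i] = nmb(r_with, r_wo, cfg.willingness_to_pay,
                          cfg.software_cost_per_exam)

    def summarise(x: np.ndarray) -> dict[str, float]:
        return {"mean": float(x.mean()),
                "q2.5": float(np.quantile(x, 0.025)),
                "q97.5": float(np.quantile(x, 0.975))}

    return {
        "draws": {"cost_with": cost_w, "qalys_with": cost_q,
                  "cost_without": cost_wo, "qalys_without": qaly_wo,
                  "nmb": nmb_vals, "prevalence": prev},
        "summary": {"cost_with": summarise(cost_w),
                    "qalys_with": summarise(cost_q),
                    "nmb": summarise(nmb_vals),
                    "p_nmb_positive": float(np.mean(nmb_vals > 0))},
        "n_draws": n_draws,
        "seed": seed,
    }
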