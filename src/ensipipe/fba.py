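"""Flux balance analysis and the carbon-source growth screen.

FBA maximizes the declared objective flux subject to steady-state mass
balance (S v = 0) and the flux bounds, with medium exchange bounds
overriding the model's. The LP is solved with the deterministic HiGHS
solver; the objective value is the contract — individual fluxes of a
degenerate optimum are not unique and are never asserted.

The carbon screen mirrors single-substrate phenotyping: starting from a base
medium with every carbon exchange closed to uptake, each panel source is
opened alone at the configured uptake rate and growth is called when the
objective exceeds ``growth_epsilon`` (default 1e-6; the objective is in
h^-1 for a biomass objective, uptake in mmol gDW^-1 h^-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import linprog

from .errors import DataError
from .models import MetabolicModel

logger = logging.getLogger(__name__)


@dataclass
class MediumSpec:
    """Exchange bounds (mmol gDW^-1 h^-1) plus the set of exchanges that
    carry a carbon source (the ones the screen opens one at a time)."""

    exchange_bounds: dict
    carbon_exchange_ids: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for rid, (lb, ub) in self.exchange_bounds.items():
            if lb > ub:
                raise DataError(f"medium entry {rid!r}: lower bound > upper bound")
        extra = self.carbon_exchange_ids - set(self.exchange_bounds)
        if extra:
            raise DataError(f"carbon exchanges missing from the medium: {sorted(extra)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MediumSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(exchange_bounds={k: (float(v[0]), float(v[1]))
                                    for k, v in d["exchange_bounds"].items()},
                   carbon_exchange_ids=set(d.get("carbon_exchange_ids", [])))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"exchange_bounds": {k: [lb, ub] for k, (lb, ub)
                                                in sorted(self.exchange_bounds.items())},
                            "carbon_exchange_ids": sorted(self.carbon_exchange_ids)}, fh)


@dataclass(frozen=True)
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class CarbonScreenResult:
    per_source: dict  # exchange id -> (objective_value, grows)
    n_tested: int
    n_growth: int
    growth_epsilon: float
    absent_sources: tuple = ()


def solve_fba(m: MetabolicModel, medium: MediumSpec | None = None) -> FluxSolution:
    """Maximize the objective flux under S v = 0 and bounds."""
    if not m.objective_reaction or m.objective_reaction not in m.reactions:
        raise DataError("model declares no valid objective reaction")
    bounds_override = dict(medium.exchange_bounds) if medium else {}
    unknown = set(bounds_override) - set(m.reactions)
    if unknown:
        raise DataError(f"medium references unknown exchanges: {sorted(unknown)}")

    rids = sorted(m.reactions)
    mids = sorted({met for r in m.reactions.values() for met in r.stoichiometry})
    midx = {mid: i for i, mid in enumerate(mids)}
    S = np.zeros((len(mids), len(rids)))
    lp_bounds = []
    c = np.zeros(len(rids))
    for j, rid in enumerate(rids):
        r = m.reactions[rid]
        for met, coef in r.stoichiometry.items():
            S[midx[met], j] = coef
        lb, ub = bounds_override.get(rid, (r.lower_bound, r.upper_bound))
        lp_bounds.append((lb, ub))
        if rid == m.objective_reaction:
            c[j] = -1.0  # linprog minimizes

    res = linprog(c, A_eq=S, b_eq=np.zeros(len(mids)), bounds=lp_bounds, method="highs")
    if res.status == 0:
        v = res.x
        residual = float(np.max(np.abs(S @ v))) if len(mids) else 0.0
        if residual > 1e-6:
            raise DataError(f"steady-state residual {residual:.2e} exceeds 1e-6")
        return FluxSolution(status="optimal", objective_value=float(-res.fun),
                            fluxes={rid: float(v[j]) for j, rid in enumerate(rids)})
    if res.status == 2:
        return FluxSolution(status="infeasible", objective_value=float("nan"), fluxes={})
    if res.status == 3:
        return FluxSolution(status="unbounded", objective_value=float("inf"), fluxes={})
    raise DataError(f"LP solver failed: {res.message}")


def carbon_source_screen(
    m: MetabolicModel,
    base_medium: MediumSpec,
    panel: Sequence[str],
    uptake_rate: float = 10.0,
    growth_epsilon: float = 1e-6,
) -> CarbonScreenResult:
    """Open each panel carbon exchange alone at ``-uptake_rate`` and test
    growth. Panel ids absent from the model are reported as no-growth and
    flagged. Results are independent of panel order."""
    per_source: dict[str, tuple[float, bool]] = {}
    absent = []
    closed = dict(base_medium.exchange_bounds)
    for cid in base_medium.carbon_exchange_ids:
        lb, ub = closed.get(cid, (0.0, 1000.0))
        closed[cid] = (0.0, ub)
    n_growth = 0
    for source in panel:
        if source not in m.reactions:
            logger.warning("panel source %s absent from the model; no growth recorded", source)
            absent.append(source)
            per_source[source] = (0.0, False)
            continue
        bounds = dict(closed)
        ub = bounds.get(source, (0.0, 1000.0))[1]
        bounds[source] = (-uptake_rate, ub)
        sol = solve_fba(m, MediumSpec(exchange_bounds=bounds))
        obj = sol.objective_value if sol.optimal else 0.0
        grows = sol.optimal and obj > growth_epsilon
        per_source[source] = (obj, grows)
        n_growth += grows
    return CarbonScreenResult(per_source=per_source, n_tested=len(panel),
                              n_growth=n_growth, growth_epsilon=growth_epsilon,
                              absent_sources=tuple(absent))


def write_screen_tsv(result: CarbonScreenResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\tobjective\tgrows\n")
        for source in sorted(result.per_source):
            obj, grows = result.per_source[source]
            fh.write(f"{source}\t{obj:.9g}\t{int(grows)}\n")
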