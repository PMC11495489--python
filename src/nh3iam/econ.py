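"""Cost-benefit accounting with annualized capital.

Net benefit per scenario is

    Net = B_societal + B_private - ( I * r(1+r)^lt / ((1+r)^lt - 1) + FVO ),

where the bracket converts an upfront investment I into an equivalent annual
cost through the capital recovery factor over the technique lifetime lt at
discount rate r, plus fixed and variable operating costs FVO.

Line items (US$ billions per annum, mid parameter level) ship as a data
catalog; the health item is computed as avoided deaths x VSL and the
greenhouse-gas item as mitigated CO2e x social cost of carbon. The scenario
without quantified costs (reduced food loss and waste) carries *absent*
costs, not zero, and reports no benefit-cost ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .inventory import DomainError
from .params import ConfigurationError

CATEGORIES = ("cost", "private_benefit", "societal_benefit")


def annualized_cost(investment: float, r: float, lifetime: float,
                    fvo: float = 0.0, r_threshold: float = 1e-9) -> float:
    """Annual cost of an investment plus operating costs (Eq. capital recovery).

    Below ``r_threshold`` the r -> 0 limit I/lt is used.
    """
    if investment < 0 or fvo < 0:
        raise DomainError("investment and operating costs must be non-negative")
    if lifetime < 1:
        raise DomainError("technique lifetime must be at least 1 year")
    if r < 0:
        raise DomainError("discount rate must be non-negative")
    if r < r_threshold:
        return investment / lifetime + fvo
    growth = (1.0 + r) ** lifetime
    return investment * r * growth / (growth - 1.0) + fvo


def health_valuation(avoided_deaths: float, vsl: float) -> float:
    """Health benefit in US$ billions/yr from avoided deaths and the VSL."""
    if avoided_deaths < 0 or vsl < 0:
        raise DomainError("avoided deaths and VSL must be non-negative")
    return avoided_deaths * vsl / 1e9


def round_half_up(value: float, decimals: int) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class CostBenefitLedger:
    """Per-scenario ledger of line items in US$ billions per annum."""

    scenario: str
    items: list[tuple[str, str, float]] = field(default_factory=list)
    costs_quantified: bool = True

    def add(self, label: str, category: str, value: float) -> None:
        if category not in CATEGORIES:
            raise ConfigurationError(f"unknown ledger category {category!r}")
        self.items.append((label, category, float(value)))

    def total(self, category: str) -> float:
        return sum(v for _, c, v in self.items if c == category)

    @property
    def total_costs(self) -> float:
        return self.total("cost")

    @property
    def total_private(self) -> float:
        return self.total("private_benefit")

    @property
    def total_societal(self) -> float:
        return self.total("societal_benefit")

    @property
    def total_benefits(self) -> float:
        return self.total_private + self.total_societal

    @property
    def net_benefit(self) -> float:
        return self.total_benefits - self.total_costs

    def benefit_cost_ratio(self) -> float:
        return benefit_cost_ratio(self)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"label": l, "category": c, "usd_billions": round_half_up(v, 1)}
                for l, c, v in self.items]
        for label, value in (
            ("Total costs", self.total_costs if self.costs_quantified else float("nan")),
            ("Total private benefits", self.total_private),
            ("Total societal benefits", self.total_societal),
            ("Total benefits", self.total_benefits),
            ("Net benefits", self.net_benefit),
        ):
            rows.append({"label": label, "category": "total",
                         "usd_billions": round_half_up(value, 1) if value == value else None})
        return pd.DataFrame(rows)


def benefit_cost_ratio(ledger: CostBenefitLedger) -> float:
    """Total benefits over total costs, rounded half-up to two decimals."""
    if not ledger.costs_quantified:
        raise DomainError(f"{ledger.scenario}: costs are not quantified, BCR undefined")
    costs = ledger.total_costs
    if costs <= 0:
        raise DomainError("benefit-cost ratio undefined for zero total costs")
    return round_half_up(ledger.total_benefits / costs, 2)


def build_ledger(scenario: str, avoided_deaths_count: float, econ_params: dict,
                 ghg_reduction_mt: float | None = None,
                 level: str = "mid") -> CostBenefitLedger:
    """Assemble the ledger for one scenario from the item catalog.

    ``avoided_deaths_count`` feeds the health item; ``ghg_reduction_mt``
    defaults to the catalog value. Levels other than mid apply the configured
    stub multipliers (reversed for negative benefit items so high >= mid >=
    low holds item-wise).
    """
    catalog = econ_params["catalog"]
    if scenario not in catalog:
        raise ConfigurationError(f"no cost-benefit catalog entry for {scenario!r}")
    entry = catalog[scenario]
    mult = econ_params["level_multipliers"]
    if level not in mult:
        raise ConfigurationError(f"unknown parameter level {level!r}")
    m = float(mult[level])
    # negative benefit items scale with the reversed multiplier so that
    # high-level benefits dominate mid dominate low, item by item
    m_neg = float(mult[{"low": "high", "high": "low"}.get(level, level)])
    r = float(econ_params["discount_rate"])
    lt = float(econ_params["lifetime_yr"])

    ledger = CostBenefitLedger(scenario=scenario)
    cost_items = entry.get("costs", {})
    ledger.costs_quantified = bool(cost_items)
    for label, spec in cost_items.items():
        investment = float(spec.get("investment", 0.0))
        fvo = float(spec.get("fvo", 0.0))
        ledger.add(label, "cost", m * annualized_cost(investment, r, lt, fvo))
    for label, value in entry.get("private_benefits", {}).items():
        value = float(value)
        ledger.add(label, "private_benefit", (m if value >= 0 else m_neg) * value)

    ghg_mt = float(entry.get("ghg_mt", 0.0)) if ghg_reduction_mt is None else float(ghg_reduction_mt)
    scc = float(econ_params["scc_usd_per_t"])
    ledger.add("ghg_mitigation", "societal_benefit", m * ghg_mt * 1e6 * scc / 1e9)
    ledger.add("human_health", "societal_benefit",
               m * health_valuation(avoided_deaths_count, float(econ_params["vsl_usd"])))
    others = float(entry.get("others", 0.0))
    ledger.add("others", "societal_benefit", (m if others >= 0 else m_neg) * others)
    return ledger


def table2_frame(ledgers: dict[str, CostBenefitLedger]) -> pd.DataFrame:
    """Scenario-by-item report mirroring the published cost-benefit table."""
    labels: list[tuple[str, str]] = []
    for ledger in ledgers.values():
        for label, cat, _ in ledger.items:
            if (label, cat) not in labels:
                labels.append((label, cat))
    rows = []
    for label, cat in labels:
        row = {"item": label, "category": cat}
        for name, ledger in ledgers.items():
            vals = [v for l, c, v in ledger.items if l == label and c == cat]
            row[name] = round_half_up(vals[0], 1) if vals else None
        rows.append(row)
    for total_label, accessor in (
        ("Total costs", "total_costs"),
        ("Total private benefits", "total_private"),
        ("Total societal benefits", "total_societal"),
        ("Total benefits", "total_benefits"),
        ("Net benefits", "net_benefit"),
    ):
        row = {"item": total_label, "category": "total"}
        for name, ledger in ledgers.items():
            if total_label == "Total costs" and not ledger.costs_quantified:
                row[name] = None
            else:
                row[name] = round_half_up(getattr(ledger, accessor), 1)
        rows.append(row)
    row = {"item": "Benefit-cost ratio", "category": "ratio"}
    for name, ledger in ledgers.items():
        row[name] = ledger.benefit_cost_ratio() if ledger.costs_quantified else None
    rows.append(row)
    return pd.DataFrame(rows)
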