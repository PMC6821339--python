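"""Monetisation of trait changes and end-to-end scenario evaluation.

Implied economic values come out of the index machinery in reference-trait
units — here grams of dry biomass per plant per unit change of the trait.
Scaling by stand density converts a one-unit trait change into a biomass
equivalent per hectare, and a biomass price turns that into currency:

    tonnes/ha = density * delta * econ_ratio / 1e6
    value/ha  = tonnes/ha * price

with density in plants/ha, delta in trait units, econ_ratio in grams per
plant per trait unit.

Which delta to monetise is a genuine modelling choice. Scenario write-ups
in this field mix conventions: an absolute gain (44 d of flowering delay)
is monetised as-is, a percent-specified cell-wall gain is monetised by its
percent figure (5, not the 0.45 percentage-point absolute change), and a
hold-unchanged constraint is monetised per unit of the trait (delta = 1).
Both that mixed "as_printed" convention and a uniform "absolute" one are
provided; reports state which was used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .core import (
    EconomicAssumptions,
    Gain,
    GeneticParameters,
    IndexSolution,
    Scenario,
    TraitPanel,
    ValidationError,
    absolute_gains,
    validate_parameters,
)
from .intensity import fraction_from_intensity

log = logging.getLogger("gainsel")


def biomass_equivalent(
    delta: float, econ_ratio: float, econ: EconomicAssumptions
) -> float:
    """Dry-biomass equivalent (tonnes/ha) of a trait change.

    ``density * delta * econ_ratio / grams_per_tonne`` — e.g. 4444 plants/ha
    x 44 d x 2.2 g per plant per day / 1e6 = 0.43 t/ha.
    """
    return econ.density * delta * econ_ratio / econ.grams_per_tonne


def monetary_value(tonnes_per_ha: float, econ: EconomicAssumptions) -> float:
    """Currency value per hectare of a biomass equivalent (unrounded)."""
    return tonnes_per_ha * econ.price


@dataclass(frozen=True)
class ScenarioReport:
    """Full output of run_scenario for one scenario.

    ``table`` has one row per panel trait in panel order with the response
    (delta, percent of mean), the index weight, the implied economic value
    and its ratio to the reference trait. ``monetization`` has one row per
    non-reference constrained trait with its biomass and currency
    equivalents.
    """

    panel: TraitPanel
    scenario: Scenario
    solution: IndexSolution
    table: pd.DataFrame
    monetization: pd.DataFrame
    econ: EconomicAssumptions
    monetization_mode: str
    mask: np.ndarray = field(repr=False, default=None)

    @property
    def name(self) -> str:
        return self.scenario.name


def _monetization_delta(gain: Gain, q_abs: float, mode: str) -> float:
    """The delta to monetise for one constrained trait (always magnitude)."""
    if mode == "absolute":
        return abs(q_abs) if gain.value != 0 else 1.0
    # "as_printed": percent-specified gains monetised by their percent figure,
    # hold-unchanged constraints per unit of the trait
    if gain.value == 0:
        return 1.0
    if gain.mode == "percent":
        return abs(gain.value)
    return abs(q_abs)


def run_scenario(
    panel: TraitPanel,
    params: GeneticParameters,
    scenario: Scenario,
    econ: EconomicAssumptions | None = None,
    psd_repair: bool = False,
    monetization_mode: str = "as_printed",
) -> ScenarioReport:
    """Evaluate one desired-gains scenario end to end.

    Deterministic pipeline: convert gains to absolute units, solve the
    restricted desired-gains index, evaluate correlated responses on all
    traits, back out implied economic values and normalise them to the
    reference trait, compute sigma_I and the required intensity, invert it
    to a selected fraction, and monetise the constrained secondary traits.
    Errors from any stage are re-raised labelled with the stage name.
    """
    if econ is None:
        econ = EconomicAssumptions()
    if monetization_mode not in ("as_printed", "absolute"):
        raise ValidationError(f"unknown monetization mode {monetization_mode!r}")

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise type(exc)(f"[{scenario.name}/{name}] {exc}") from exc

    params = stage("validate_parameters", validate_parameters, panel, params,
                   psd_repair=psd_repair)
    scenario = stage("scenario", scenario.validate, panel)
    Q, mask = stage("absolute_gains", absolute_gains, scenario, panel)
    log.info("%s: %d desired gains on %d traits", scenario.name, len(mask), panel.n)
    b = stage("restricted_gain_weights", engine.restricted_gain_weights,
              params, Q, mask)
    Q_star = stage("correlated_responses", engine.correlated_responses, params, b)
    a = stage("implied_economic_values", engine.implied_economic_values, params, b)
    try:
        ratios = engine.normalize_economic_values(a, panel.reference_index)
    except ZeroDivisionError:
        # reference trait carries no implied value for this index; ratios
        # (and hence monetisation) are undefined, not an error
        log.warning(
            "%s: reference trait %s has zero implied economic value; "
            "economic ratios are undefined",
            scenario.name, panel.names[panel.reference_index],
        )
        ratios = np.full(panel.n, np.nan)
    sigma_I, i = stage("index_sd_and_intensity", engine.index_sd_and_intensity,
                       params, b)
    p = stage("fraction_from_intensity", fraction_from_intensity, i)
    pct = stage("relative_change", engine.relative_change, Q_star, panel)

    solution = IndexSolution(b=b, a=a, Q_star=Q_star, sigma_I=sigma_I, i=i, p=p)
    table = pd.DataFrame(
        {
            "trait": panel.names,
            "unit": panel.units,
            "current_mean": panel.means,
            "delta": Q_star,
            "pct_change": pct,
            "weight_b": b,
            "econ_value_a": a,
            "econ_ratio": ratios,
        }
    )

    by_trait = {g.trait: g for g in scenario.gains}
    ref = panel.names[panel.reference_index]
    rows = []
    for q_abs, j in zip(Q, mask):
        trait = panel.names[j]
        if trait == ref:
            continue
        gain = by_trait[trait]
        delta = _monetization_delta(gain, q_abs, monetization_mode)
        ratio = abs(float(ratios[j]))
        if not np.isfinite(ratio):
            continue
        tonnes = biomass_equivalent(delta, ratio, econ)
        rows.append(
            {
                "trait": trait,
                "delta_monetized": delta,
                "abs_econ_ratio": ratio,
                "tonnes_per_ha": tonnes,
                "value_per_ha": monetary_value(tonnes, econ),
            }
        )
    monetization = pd.DataFrame(
        rows,
        columns=["trait", "delta_monetized", "abs_econ_ratio",
                 "tonnes_per_ha", "value_per_ha"],
    )
    log.info(
        "%s: sigma_I=%.4f, i=%.4f, select top %.2f%%",
        scenario.name, sigma_I, i, 100 * p,
    )
    return ScenarioReport(
        panel=panel, scenario=scenario, solution=solution, table=table,
        monetization=monetization, econ=econ, monetization_mode=monetization_mode,
        mask=mask,
    )


def refine_scenario(scenario: Scenario, hold_constant: list[str]) -> Scenario:
    """Refine a scenario by holding additional traits unchanged.

    Appends zero-gain (absolute) constraints for ``hold_constant`` and
    suffixes the name with ``*``; the original scenario is untouched. A
    trait already constrained with a nonzero gain cannot also be held.
    """
    if not hold_constant:
        return Scenario(scenario.name, scenario.gains)
    existing = {g.trait: g for g in scenario.gains}
    new_gains = list(scenario.gains)
    for trait in hold_constant:
        if trait in existing and existing[trait].value != 0:
            raise ValidationError(
                f"trait {trait!r} already has a nonzero desired gain; cannot hold constant"
            )
        if trait not in existing:
            new_gains.append(Gain(trait=trait, value=0.0, mode="absolute"))
    return Scenario(scenario.name + "*", new_gains)


def compare_scenarios(*reports: ScenarioReport) -> pd.DataFrame:
    """Side-by-side responses (delta and %) for scenarios on one panel.

    Adds a ``sign_flip`` column flagging traits whose response changes sign
    between any pair of scenarios — refinements routinely reverse
    correlated responses of unconstrained traits.
    """
    if not reports:
        raise ValueError("no reports to compare")
    panel = reports[0].panel
    for r in reports[1:]:
        if r.panel.names != panel.names:
            raise ValidationError("reports use different trait panels")
    out = pd.DataFrame({"trait": panel.names, "unit": panel.units,
                        "current_mean": panel.means})
    deltas = []
    for r in reports:
        out[f"delta_{r.name}"] = r.table["delta"].to_numpy()
        out[f"pct_{r.name}"] = r.table["pct_change"].to_numpy()
        deltas.append(r.table["delta"].to_numpy())
    D = np.column_stack(deltas)
    out["sign_flip"] = (D.max(axis=1) > 0) & (D.min(axis=1) < 0)
    return out
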