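"""Brute-force day-resolution inventory oracle, independent of the package.

Re-implements the inventory rules from scratch with the decay clock run in
364 one-day steps: shipments land at the start of their week, every cohort
decays day by day, the weekly record is taken after the last daily decay of
each week (so at exactly the same decay depth as the weekly engine), and
the week's demand is then served FIFO under the banded multi-dose rule.
Demand service and record epochs stay weekly because the model defines
demand as a constant weekly quantity; only the decay integration is
refined. Used to cross-check the weekly engine's bookkeeping.
"""

import math

GAS_R = 8.314


def arrhenius_rate(temp_c, anchor_low=(35.0, 0.80, 91.0), anchor_high=(45.0, 0.20, 91.0)):
    """Closed-form rate constant from the two quarter-decay anchors, 1/day."""
    (t1c, f1, d1), (t2c, f2, d2) = anchor_low, anchor_high
    k1 = -math.log(f1) / d1
    k2 = -math.log(f2) / d2
    t1, t2 = t1c + 273.15, t2c + 273.15
    ea = GAS_R * math.log(k2 / k1) / (1.0 / t1 - 1.0 / t2)
    a = k1 * math.exp(ea / (GAS_R * t1))
    return a * math.exp(-ea / (GAS_R * (temp_c + 273.15)))


def _multiplier(strength):
    if strength >= 0.85:
        return 1
    if strength >= 0.54:
        return 2
    if strength >= 0.33:
        return 3
    return None


def daily_simulation(annual_doses, shipments_per_year, temp_c, weekly_demand):
    """One simulated year at day resolution; returns the 52 weekly ratios."""
    k = arrhenius_rate(temp_c)
    daily_factor = math.exp(-k)
    ship_weeks = [52 * i // shipments_per_year for i in range(shipments_per_year)]
    per_shipment = round(annual_doses / shipments_per_year)
    cohorts = []  # [doses, strength]
    ratios = []
    for day in range(364):
        week, day_of_week = divmod(day, 7)
        if day_of_week == 0 and week in ship_weeks and per_shipment > 0:
            cohorts.append([per_shipment, 1.0])
        for cohort in cohorts:
            cohort[1] *= daily_factor
        if day_of_week == 6:
            effective = sum(
                doses // _multiplier(s) for doses, s in cohorts if _multiplier(s)
            )
            upcoming = [w for w in ship_weeks if w > week]
            next_week = min(upcoming) if upcoming else 52 + min(ship_weeks)
            ratios.append(effective / (weekly_demand * (next_week - week)))
            patients = math.ceil(weekly_demand)
            for cohort in cohorts:
                if patients == 0:
                    break
                mult = _multiplier(cohort[1])
                if mult is None:
                    continue
                served = min(patients, cohort[0] // mult)
                cohort[0] -= served * mult
                patients -= served
            cohorts = [c for c in cohorts if c[0] > 0 and c[1] >= 0.33]
    return ratios
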