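"""Single source of truth for model default constants.

Every default used by the simulator lives here, with a note on where the
number comes from (Zanzibar CMS records, DHS-style survey estimates, or a
derivation from another constant). Engine code imports these; no literals
are scattered elsewhere.
"""

# --- Physical / kinetic constants -------------------------------------------

#: Ideal gas constant, J/(mol K).
GAS_CONSTANT = 8.314

#: Stability anchors for injectable oxytocin at pH 4.5: after one quarter of
#: storage (13 weeks = 91 days) dose strength falls to 80% at 35 degC and to
#: 20% at 45 degC. The Arrhenius pair (A, Ea) is calibrated to reproduce
#: these two points exactly; the 30 degC (~90%) and 40 degC (~60%) quarter
#: points then serve as consistency checks (the four points are not mutually
#: Arrhenius-consistent, so only two can be fit exactly).
ANCHOR_LOW = (35.0, 0.80, 91.0)   # (temp degC, remaining fraction, days)
ANCHOR_HIGH = (45.0, 0.20, 91.0)

DAYS_PER_WEEK = 7
WEEKS_PER_YEAR = 52
DAYS_PER_QUARTER = 91  # 13 weeks

#: Effective-dose strength bands: full credit at >=85% strength, double
#: dosing (half credit) at 54-85%, triple dosing (one-third credit) at
#: 33-54%, written off below 33%.
FULL_STRENGTH_MIN = 0.85
DOUBLE_DOSE_MIN = 0.54
TRIPLE_DOSE_MIN = 0.33

# --- Facility-delivery access -----------------------------------------------

#: Odds ratios for delivering at a health facility (Sub-Saharan Africa
#: survey estimates): richest wealth quintile, literacy, rural residence.
OR_WEALTH_RICHEST = 2.55
OR_LITERACY = 1.99
OR_RURAL = 0.82

#: Facility-delivery proportion at the literacy extremes: 41% for a fully
#: illiterate population, 53% for a fully literate one. These pin the
#: anchored-linear access mode.
ACCESS_ILLITERATE = 0.41
ACCESS_LITERATE = 0.53

#: Zanzibar adult female literacy rate.
DEFAULT_LITERACY = 0.67

#: Calibration target for the logistic access mode: ~50% of Zanzibari women
#: currently deliver at a facility.
DEFAULT_ACCESS_TARGET = 0.50

#: Population composition defaults where no finer estimate exists: wealth
#: quintiles 20% each, half the population rural, half within 5 km of an
#: EmONC facility.
DEFAULT_WEALTH_SHARES = (0.2, 0.2, 0.2, 0.2, 0.2)
DEFAULT_RURAL_SHARE = 0.50
DEFAULT_WITHIN_5KM_SHARE = 0.50

# --- Demand ------------------------------------------------------------------

#: One prophylactic dose per facility birth; 2% of women develop postpartum
#: hemorrhage and require four additional therapeutic doses. Hence the
#: expected demand multiplier 1 + 0.02*4 = 1.08 doses per facility birth.
PROPHYLACTIC_DOSES_PER_BIRTH = 1
PPH_RATE = 0.02
EXTRA_DOSES_PER_PPH = 4
THERAPEUTIC_DOSE_IU = 10

#: Annual national requirement at universal facility delivery (doses/year),
#: from CMS-level modelling; the annual-births default is derived from it.
FULL_ACCESS_REQUIREMENT = 53_000

#: Derived: annual births such that universal facility delivery demands
#: exactly FULL_ACCESS_REQUIREMENT doses: 53,000 / 1.08 = 49,074.
DEFAULT_ANNUAL_BIRTHS = 49_074

#: Zanzibar population growth, fraction per year.
DEFAULT_GROWTH_RATE = 0.03

# --- Supply ------------------------------------------------------------------

#: Actual annual oxytocin order placed by the Ministry of Health through the
#: Central Medical Store.
DEFAULT_ANNUAL_DOSES = 100_000

#: Semiannual restocking of the CMS inventory.
DEFAULT_SHIPMENTS_PER_YEAR = 2

#: Cold-chain-compliant ambient storage temperature, degC. Keeps degradation
#: negligible over a shipment cycle, the national-baseline storage condition.
DEFAULT_STORAGE_TEMP_C = 25.0

#: minimal-supply answers are reported to the nearest hundred doses.
SUPPLY_ROUNDING = 100
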