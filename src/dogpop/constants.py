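"""Published constants used throughout the pipeline.

Every number here is a fixed input of the analysis (study design constants,
externally supplied subpopulation sizes, and the informative prior on the
national dog population).  They are collected in one place so that each can
be overridden from the run configuration and so that logs can record the
values actually used.
"""

from __future__ import annotations

#: Number of households in Britain used to scale dogs-per-household rates.
N_HOUSEHOLDS = 25.9e6

#: Veterinary practices on the national register.
N_PRACTICES = 3638

#: Mean number of practices represented by a single survey response.
PRACTICES_PER_RESPONSE = 1.32

#: Effective number of independent practices used as the multiplier for the
#: veterinary subpopulation.  The source analysis states 2550 even though
#: 3638 / 1.32 ≈ 2756; both conventions are exposed, 2550 is the default.
EFFECTIVE_PRACTICES = 2550

#: Number of valid veterinary-practice responses behind the size distribution.
N_PRACTICE_RESPONSES = 77

#: Fixed size of the insured-dog subpopulation (industry-body estimate,
#: supplied without an interval).
INSURED_SUBPOP = 2_000_000

#: Living Kennel-Club-registered subpopulation: survival-adjusted registry
#: summary, expressed as a Normal(mean, sd) with sd = CI width / 3.92.
KC_SUBPOP_MEAN = 2_116_871
KC_SUBPOP_CI = (1_696_647, 2_425_060)
KC_SUBPOP_SD = (KC_SUBPOP_CI[1] - KC_SUBPOP_CI[0]) / 3.92  # 185,820.7

#: Informative prior on the total owned-dog population (an earlier national
#: telephone-survey estimate): mean 10.5M, 95% CI 9.6-11.4M.
MURRAY_PRIOR_MEAN = 10.5e6
MURRAY_PRIOR_CI = (9.6e6, 11.4e6)
MURRAY_PRIOR_SD = (MURRAY_PRIOR_CI[1] - MURRAY_PRIOR_CI[0]) / 3.92  # 459,184

#: Quota of valid responses per telephone-directory area.
SURVEY_QUOTA = 30

#: Practice-survey sampling frame and respondents by country.
COUNTRY_FRAME = {
    "England": 2985,
    "Northern Ireland": 90,
    "Scotland": 334,
    "Wales": 203,
    "Isle of Man": 8,
    "Channel Islands": 13,
}
COUNTRY_RESPONDENTS = {
    "England": 72,
    "Northern Ireland": 0,
    "Scotland": 2,
    "Wales": 3,
    "Isle of Man": 0,
    "Channel Islands": 0,
}

#: Frame and respondents by settlement (urban-rural) class.
URBAN_RURAL_FRAME = {
    "Urban": 2546,
    "Town or Fringe": 675,
    "Village": 231,
    "Hamlet and Isolated Dwelling": 160,
}
URBAN_RURAL_RESPONDENTS = {
    "Urban": 58,
    "Town or Fringe": 13,
    "Village": 3,
    "Hamlet and Isolated Dwelling": 3,
}
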