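"""Fixed 15-state space of the NAFL/NASH cohort model.

The disease is tracked jointly by steatosis type (benign NAFL vs.
inflammatory NASH) and fibrosis stage.  Early fibrosis (F0-F2) is split by
NAFL/NASH; advanced fibrosis (F3) and cirrhosis (F4) are not, because
outcomes there are driven by cirrhosis severity alone.  ``F4_Y1`` is a
one-cycle tunnel (first year of compensated cirrhosis, the point at which a
curative therapy is administered); the two transplant states are one-cycle
tunnels into the post-transplant state.  ``DEATH`` is absorbing.
"""

from __future__ import annotations

STATES: tuple[str, ...] = (
    "NAFL_F0",
    "NAFL_F1",
    "NAFL_F2",
    "NASH_F0",
    "NASH_F1",
    "NASH_F2",
    "F3",
    "F4_Y1",
    "F4_LATER",
    "DC",
    "HCC",
    "LT_DC",
    "LT_HCC",
    "PLT",
    "DEATH",
)

N_STATES = len(STATES)
IDX: dict[str, int] = {name: i for i, name in enumerate(STATES)}

LIVE_STATES: tuple[str, ...] = STATES[:-1]

#: early-fibrosis disease states, split by NAFL/NASH
NAFL_EARLY = ("NAFL_F0", "NAFL_F1", "NAFL_F2")
NASH_EARLY = ("NASH_F0", "NASH_F1", "NASH_F2")
EARLY_STATES = NAFL_EARLY + NASH_EARLY

F4_STATES = ("F4_Y1", "F4_LATER")
LT_TUNNELS = ("LT_DC", "LT_HCC")

#: health-state utility groups as elicited (F0-F2 share one utility)
UTILITY_GROUP: dict[str, str] = {
    **{s: "early" for s in EARLY_STATES},
    "F3": "F3",
    "F4_Y1": "F4",
    "F4_LATER": "F4",
    "DC": "DC",
    "HCC": "HCC",
    "LT_DC": "LT",
    "LT_HCC": "LT",
    "PLT": "LT",
}

#: annual direct-medical-cost groups (transplant year is costed separately
#: from later post-transplant years)
COST_GROUP: dict[str, str] = {
    "NAFL_F0": "NAFL_F0",
    "NAFL_F1": "NAFL_F1",
    "NAFL_F2": "NAFL_F2",
    "NASH_F0": "NASH_F0",
    "NASH_F1": "NASH_F1",
    "NASH_F2": "NASH_F2",
    "F3": "F3",
    "F4_Y1": "F4",
    "F4_LATER": "F4",
    "DC": "DC",
    "HCC": "HCC",
    "LT_DC": "LT_Y1",
    "LT_HCC": "LT_Y1",
    "PLT": "PLT",
}

#: cardiovascular-mortality hazard-ratio groups (differentiated between
#: F0-F2, F3 and F4; states at or beyond cirrhosis use the F4 group)
CV_HR_GROUP: dict[str, str] = {
    **{s: "F0_F2" for s in EARLY_STATES},
    "F3": "F3",
    "F4_Y1": "F4",
    "F4_LATER": "F4",
    "DC": "F4",
    "HCC": "F4",
    "LT_DC": "F4",
    "LT_HCC": "F4",
    "PLT": "F4",
}

#: liver-related excess mortality groups (relative risk applies from
#: advanced fibrosis onward; transplant-year states share one RR)
LIVER_RR_GROUP: dict[str, str] = {
    "F3": "F3",
    "F4_Y1": "F4",
    "F4_LATER": "F4",
    "DC": "DC",
    "HCC": "HCC",
    "LT_DC": "LT",
    "LT_HCC": "LT",
    "PLT": "PLT",
}

STRATEGIES: tuple[str, ...] = ("lifestyle", "small_molecule", "biologic", "curative")
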