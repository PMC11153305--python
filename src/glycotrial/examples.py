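"""Worked-example category counts.

These cell specifications encode the published 12-month results of a
randomised primary-care trial of a monthly fasting-mimicking diet (FMD)
added to usual care in type 2 diabetes, in which 43 FMD and 39 control
participants were classifiable at 12 months (intention to treat) and 30 vs
39 per protocol. They are used throughout the documentation and regression
tests as inputs to :func:`glycotrial.simulate.cohort_from_counts`.

Only the three marginal tables per arm (medication change, HbA1c change,
glycaemic management) and the stopped/additional-medication counts were
published; the joint (medication x HbA1c) assignment below is one feasible
solution consistent with all of them, including the two intervention-arm
participants who used less medication yet deteriorated in HbA1c (the
tie-break cell).

Marginals realised by ``ITT_12M`` (decreased/stable/increased,
improved/stable/deteriorated):

* medication change — FMD 17/22/4, control 2/20/17
* HbA1c change — FMD 18/19/6, control 6/22/11
* glycaemic management — FMD 23/10/10, control 3/13/23
* medication stopped — FMD 7, control 2; additional drug — FMD 1, control 10

and by ``PP_12M``: medication 14/14/2 vs 2/20/17, HbA1c 15/11/4 vs
6/22/11, glycaemic management 19/5/6 vs 3/13/23.
"""

from __future__ import annotations

from .simulate import CellSpec

# (medication action, hba1c category, n participants)
ITT_12M: dict[str, list[CellSpec]] = {
    "FMD": [
        ("stop", "improved", 4),
        ("stop", "stable", 3),
        ("lower", "improved", 4),
        ("lower", "stable", 4),
        ("lower", "deteriorated", 2),  # tie-break cell
        ("stable", "improved", 8),
        ("stable", "stable", 10),
        ("stable", "deteriorated", 4),
        ("add", "improved", 1),
        ("raise", "improved", 1),
        ("raise", "stable", 2),
    ],
    "control": [
        ("stop", "deteriorated", 2),
        ("stable", "improved", 3),
        ("stable", "stable", 13),
        ("stable", "deteriorated", 4),
        ("add", "improved", 3),
        ("add", "stable", 5),
        ("add", "deteriorated", 2),
        ("raise", "stable", 4),
        ("raise", "deteriorated", 3),
    ],
}

PP_12M: dict[str, list[CellSpec]] = {
    "FMD": [
        ("lower", "improved", 7),
        ("lower", "stable", 5),
        ("lower", "deteriorated", 2),
        ("stable", "improved", 7),
        ("stable", "stable", 5),
        ("stable", "deteriorated", 2),
        ("add", "improved", 1),
        ("raise", "stable", 1),
    ],
    "control": ITT_12M["control"],
}
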