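"""Caregiver questionnaire registry: subscales, availability, analysis masks.

Availability follows the study design: the sensory questionnaires (SPM,
SEQ) are collected for every group; the ASD diagnostic instruments
(ADOS, ADI-R) only for children with a primary ASD diagnosis (ASD and
ASD+ADHD groups); the ADHD rating scales (Conners, DuPaul) are collected
broadly but their correlation screens include only children whose primary
diagnosis is ADHD (the comorbid ASD+ADHD group is excluded from those
analyses).

Bonferroni multipliers equal the number of subscales screened per
instrument: 7 for the SPM (its total-sensory-systems composite is not
screened), 9 for the SEQ.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

GROUPS = ("TDC", "ASD", "ADHD", "ASD+ADHD")
ASD_GROUPS = ("ASD", "ASD+ADHD")


@dataclass(frozen=True)
class Instrument:
    name: str
    subscales: tuple[str, ...]
    multiplier: int
    available_groups: tuple[str, ...]
    analysis_mask: str  # "all" | "asd" | "adhd_only"

    def columns(self) -> list[str]:
        return [f"{self.name}_{s}" for s in self.subscales]


INSTRUMENTS: dict[str, Instrument] = {
    "spm": Instrument(
        "spm",
        ("social_participation", "vision", "hearing", "touch",
         "body_awareness", "balance_motion", "planning_ideas"),
        7, GROUPS, "all"),
    "seq": Instrument(
        "seq",
        ("total_hyper", "total_hypo", "total_seeking",
         "social_hyper", "social_hypo", "social_seeking",
         "nonsocial_hyper", "nonsocial_hypo", "nonsocial_seeking"),
        9, GROUPS, "all"),
    "ados": Instrument(
        "ados",
        ("total", "communication_social", "social_interaction",
         "stereotyped_behaviors"),
        4, ASD_GROUPS, "asd"),
    "adi_r": Instrument(
        "adi_r",
        ("reciprocal_social_interaction", "communication",
         "repetitive_behavior"),
        3, ASD_GROUPS, "asd"),
    "conners": Instrument(
        "conners", ("inattention", "hyperactivity"), 2, GROUPS, "adhd_only"),
    "dupaul": Instrument(
        "dupaul", ("inattention", "hyperactivity"), 2, GROUPS, "adhd_only"),
}

#: The three correlation screens, in study order.
SCREENS = {
    "sensory": ("spm", "seq"),
    "asd": ("ados", "adi_r"),
    "adhd": ("conners", "dupaul"),
}


def mask_for(name: str, groups: pd.Series) -> pd.Series:
    """Boolean analysis mask over a Series of group labels."""
    if name == "all":
        return pd.Series(True, index=groups.index)
    if name == "asd":
        return groups.isin(ASD_GROUPS)
    if name == "adhd_only":
        return groups == "ADHD"
    raise ValueError(f"unknown mask {name!r}")
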