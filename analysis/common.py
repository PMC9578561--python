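"""Shared study definition for the analysis drivers.

A four-chemical demonstration panel with effect profiles spanning the
archetypes seen in organophosphorus screens: a potent cholinergic-like
chemical (stickiness at low concentration, lethality at the top), a
motility-suppressing chemical (reduced speed in blue light and more rest),
a weak hyperactivity-only chemical, and a negative control.  Ground truth
is known, so every downstream table can be checked against design.
"""

from pathlib import Path

from planartox import schema as sc
from planartox.config import RunConfig
from planartox.synthetic_screen import GroundTruth, HillEffect, StudyDesign

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 17

# Ellman ground truth per chemical: (IC50 uM, slope b); the null control has
# no inhibition within the tested range.
ELLMAN_TRUTH = {
    "dv_like": (0.05, 1.2),
    "cpf_like": (0.5, 1.5),
    "ace_like": (500.0, 1.0),
}


def panel_truth() -> GroundTruth:
    gt = GroundTruth()
    for wt in sc.WORM_TYPES:
        for day in sc.DAYS:
            # potent cholinergic-like profile
            gt.set("dv_like", "stickiness", wt, day, HillEffect(0.85, 0.8, 2.0))
            gt.set("dv_like", "body_shape", wt, day, HillEffect(0.9, 5.0, 2.5))
            gt.set("dv_like", "lethality", wt, day,
                   HillEffect(0.95 if day == 12 else 0.35, 20.0, 4.0))
            # motility suppressor
            gt.set("cpf_like", "speed_blue1", wt, day,
                   HillEffect(160.0, 4.0, 2.0, "-"))
            gt.set("cpf_like", "speed_blue2", wt, day,
                   HillEffect(160.0, 4.0, 2.0, "-"))
            gt.set("cpf_like", "resting", wt, day, HillEffect(120.0, 6.0, 2.0))
            if day == 12:
                gt.set("cpf_like", "scrunching", wt, day,
                       HillEffect(0.7, 8.0, 2.0))
            # weak hyperactivity only at the top of the range
            gt.set("ace_like", "speed_dark2_2", wt, day,
                   HillEffect(130.0, 25.0, 3.0))
            gt.set("ace_like", "speed_dark2_3", wt, day,
                   HillEffect(130.0, 25.0, 3.0))
    return gt


def panel_config(seed: int = SEED) -> RunConfig:
    return RunConfig(
        seed=seed,
        outdir=str(RESULTS),
        design=StudyDesign(),  # 10 quarter-log concentrations, 31.6 uM top
        truth=panel_truth(),
        chemicals=["dv_like", "cpf_like", "ace_like", "control"],
        B_select=100,
        B_final=500,
        k_clusters=4,
    )
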