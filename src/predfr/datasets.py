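"""Published reference values from a cotton-field study of *Lygus pratensis*
predators (Alar, Xinjiang).

These are the printed summary statistics of that study — the per-taxon
gut-content screening counts for 23 predatory natural-enemy species, and the
functional-response parameter estimates for the four spider species that
screened positive — included so worked examples, report reproduction and
cross-checks can run without any external download. The underlying
bottle-level predation counts were not published; use
:mod:`predfr.synthetic_data` to generate statistically comparable trials.
"""

from __future__ import annotations

from .functional_response import HollingFit, PreyStage, ResponseType
from .gut_detection import DetectionRecord, DetectionTable

__all__ = [
    "detection_survey",
    "spider_holling_fits",
    "spider_cubic_coefficients",
    "community_counts",
    "ORDER_TO_CLASS",
]

#: Arthropod class for each order appearing in the survey.
ORDER_TO_CLASS = {
    "Diptera": "Insecta",
    "Coleoptera": "Insecta",
    "Neuroptera": "Insecta",
    "Hemiptera": "Insecta",
    "Lepidoptera": "Insecta",
    "Thysanoptera": "Insecta",
    "Araneae": "Arachnida",
    "Acarina": "Arachnida",
}

# (order, family, species, collected, detected, positive)
_DETECTION_ROWS = [
    ("Diptera", "Syrphidae", "Sphaerophoria rueppeuii", 33, 33, 0),
    ("Diptera", "Syrphidae", "Eupeodes luniger", 17, 16, 0),
    ("Diptera", "Syrphidae", "Scaeva pyrastri", 29, 29, 0),
    ("Coleoptera", "Coccinellidae", "Hippodamia variegata", 113, 109, 0),
    ("Coleoptera", "Coccinellidae", "Coccinella undecimpunctata", 30, 28, 0),
    ("Coleoptera", "Coccinellidae", "Oenopia conglobata", 23, 23, 0),
    ("Neuroptera", "Chrysopidae", "Chrysoperla nipponensis", 39, 38, 0),
    ("Neuroptera", "Chrysopidae", "Chrysoperla carnea", 62, 62, 0),
    ("Hemiptera", "Miridae", "Deraeocoris punctulatus", 101, 100, 0),
    ("Araneae", "Philodromidae", "Thanatus vulgaris", 17, 16, 0),
    ("Araneae", "Philodromidae", "Philodromus alascensis", 21, 19, 0),
    ("Araneae", "Philodromidae", "Philodromus cespitum", 22, 19, 0),
    ("Araneae", "Thomisidae", "Ebrechtella tricuspidata", 69, 66, 28),
    ("Araneae", "Thomisidae", "Xysticus ephippiatus", 37, 37, 7),
    ("Araneae", "Thomisidae", "Spiracme striatipes", 13, 13, 0),
    ("Araneae", "Lycosidae", "Lycosa ishikariana", 15, 15, 0),
    ("Araneae", "Lycosidae", "Pardosa astrigera", 14, 14, 0),
    ("Araneae", "Linyphiidae", "Hylyphantes graminicola", 51, 51, 6),
    ("Araneae", "Linyphiidae", "Microlinyphia pusilla", 34, 32, 0),
    ("Araneae", "Theridiidae", "Steatoda albomaculata", 18, 18, 0),
    ("Araneae", "Tetragnathidae", "Tetragnatha extensa", 29, 29, 0),
    ("Araneae", "Oxyopidae", "Oxyopes sertatus", 11, 11, 4),
    ("Araneae", "Araneidae", "Neoscona adianta", 28, 28, 0),
]

# Published disc-equation estimates: all four spiders classified Type II on
# both prey stages. (predator, stage, a_prime, Th, r_squared)
_FIT_ROWS = [
    ("E. tricuspidata", PreyStage.NYMPH_4_5, 1.276, 0.023, 0.975),
    ("X. ephippiatus", PreyStage.NYMPH_4_5, 1.256, 0.037, 0.961),
    ("H. graminicola", PreyStage.NYMPH_4_5, 1.067, 0.045, 0.955),
    ("O. sertatus", PreyStage.NYMPH_4_5, 1.339, 0.022, 0.976),
    ("E. tricuspidata", PreyStage.ADULT, 1.231, 0.025, 0.969),
    ("X. ephippiatus", PreyStage.ADULT, 1.290, 0.041, 0.962),
    ("H. graminicola", PreyStage.ADULT, 1.085, 0.049, 0.951),
    ("O. sertatus", PreyStage.ADULT, 1.206, 0.024, 0.968),
]

# Published cubic type-determination coefficients (a, b, c, d, r_squared);
# every b is negative, hence the uniform Type II call.
_CUBIC_ROWS = [
    ("E. tricuspidata", PreyStage.NYMPH_4_5, 0.961, -0.008, 0.0006, -8.642e-7, 0.733),
    ("X. ephippiatus", PreyStage.NYMPH_4_5, 1.321, -0.029, 0.002, -3.901e-5, 0.774),
    ("H. graminicola", PreyStage.NYMPH_4_5, 0.884, -0.019, 0.0002, -3.211e-6, 0.727),
    ("O. sertatus", PreyStage.NYMPH_4_5, 1.018, -0.012, 0.001, -9.631e-6, 0.853),
    ("E. tricuspidata", PreyStage.ADULT, 1.021, -0.021, 0.001, -2.778e-5, 0.647),
    ("X. ephippiatus", PreyStage.ADULT, 1.056, -0.027, 0.0005, -8.642e-6, 0.821),
    ("H. graminicola", PreyStage.ADULT, 1.292, -0.105, 0.005, -8.877e-5, 0.831),
    ("O. sertatus", PreyStage.ADULT, 0.991, -0.016, 0.001, -1.272e-5, 0.661),
]

#: Prey densities per bottle used in the predation trials.
TRIAL_DENSITIES = (5, 10, 15, 20, 25, 30)
#: Replicate bottles per density treatment.
TRIAL_REPLICATES = 4
#: Predator-prey exposure time, days.
TRIAL_EXPOSURE_T = 1.0


def detection_survey() -> DetectionTable:
    """The published gut-content screening table (23 taxa, 826 collected)."""
    return DetectionTable(
        records=tuple(DetectionRecord(*row) for row in _DETECTION_ROWS)
    )


def spider_holling_fits(
    prey_stage: PreyStage | str | None = None,
) -> list[HollingFit]:
    """Published Type II disc-equation estimates for the four spider species.

    Optionally filter to one prey stage. ``n_points`` reflects the study
    design of 6 densities x 4 replicates.
    """
    stage = PreyStage(prey_stage) if prey_stage is not None else None
    return [
        HollingFit(
            model=ResponseType.II,
            attack_rate=a,
            handling_time=th,
            exposure_T=TRIAL_EXPOSURE_T,
            r_squared=r2,
            n_points=len(TRIAL_DENSITIES) * TRIAL_REPLICATES,
            converged=True,
            predator_id=pred,
            prey_stage=ps,
        )
        for pred, ps, a, th, r2 in _FIT_ROWS
        if stage is None or ps is stage
    ]


def spider_cubic_coefficients(
    prey_stage: PreyStage | str | None = None,
) -> list[dict]:
    """Published cubic type-determination coefficients as dicts."""
    stage = PreyStage(prey_stage) if prey_stage is not None else None
    return [
        {
            "predator_id": pred,
            "prey_stage": ps,
            "a": a, "b": b, "c": c, "d": d,
            "r_squared": r2,
        }
        for pred, ps, a, b, c, d, r2 in _CUBIC_ROWS
        if stage is None or ps is stage
    ]


def community_counts() -> list[tuple[str, str, int]]:
    """(class, species, collected count) triples for composition summaries."""
    return [
        (ORDER_TO_CLASS[order], species, collected)
        for order, _family, species, collected, _det, _pos in _DETECTION_ROWS
    ]
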