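"""Shared constants and the cohort/gradient stage used by several drivers.

Every driver recomputes deterministically from SEED rather than passing
large intermediates around; a full cohort embedding takes ~2 s.
"""

from pathlib import Path

from lbdgrad.datatypes import AnalysisConfig
from lbdgrad.gradients import embed_cohort
from lbdgrad.synthetic import make_cohort

SEED = 0
N_REGIONS = 200
RESULTS = Path(__file__).resolve().parent.parent / "results"
CONFIG = AnalysisConfig(n_components=10, seed=SEED)


def simulated_cohort():
    return make_cohort(seed=SEED, n_regions=N_REGIONS)


def cohort_with_gradients():
    cohort, template, latent = simulated_cohort()
    template_grads, aligned = embed_cohort(
        cohort.matrices, cohort.subjects_in("HC"), CONFIG
    )
    return cohort, template_grads, aligned, latent
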