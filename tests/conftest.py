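import numpy as np
import pytest

from aridphen.types import TruthParams

# Published per-accession parameter sets for the transpiration-rate response
# to vapour pressure deficit (intercept1, slope1, TR_bp kPa, slope2).
ACCESSION_TR_PARAMS = {
    "Marina di Andora": (27.08, 17.82, 2.52, -22.11),
    "Castel Maggiore": (-5.19, 31.43, 2.97, 4.73),
    "Zambana": (10.08, 21.35, 1.93, -2.79),
    "Sesto Fiorentino": (-0.34, 33.52, 1.52, 12.92),
}


def tr_truth(accession: str, **kwargs) -> TruthParams:
    i1, s1, x0, s2 = ACCESSION_TR_PARAMS[accession]
    return TruthParams(i1, s1, x0, s2, **kwargs)


@pytest.fixture
def ftsw_truth() -> TruthParams:
    """Noiseless water-use-vs-FTSW drydown truth: ~250 g/day plateau,
    breakpoint at FTSW 0.25, 2500 g transpirable pool."""
    return TruthParams(5.0, 980.0, 0.25, 10.0, noise_sd=0.0, ttsw=2500.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
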