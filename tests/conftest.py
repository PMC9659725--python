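import math

import numpy as np
import pandas as pd
import pytest

from emosig.emotionality import DEFAULT_MEASURES


def behavior_row(animal, group, session, measure, value, censored=False):
    test = {s.measure: s.test for s in DEFAULT_MEASURES}[measure]
    return {
        "animal": animal,
        "group": group,
        "session": session,
        "test": test,
        "measure": measure,
        "value": value,
        "censored": censored,
    }


@pytest.fixture
def unit_reference_cohort():
    """Two control animals per measure giving mu = 0, sigma = sqrt(2),
    plus one treated animal with hand-chosen values so its per-test
    z-scores are exactly (-1, +2, +1): EPM open-arm values +sqrt(2)
    (direction -1), NSF latency 2*sqrt(2) (direction +1), grooming
    -sqrt(2) (direction -1)."""
    s2 = math.sqrt(2.0)
    rows = []
    for animal, sign in (("c1", -1.0), ("c2", +1.0)):
        for spec in DEFAULT_MEASURES:
            rows.append(behavior_row(animal, "Veh/Veh", "W5", spec.measure, sign * 1.0))
    rows += [
        behavior_row("t1", "Cort/Veh", "W5", "open_arm_time", s2),
        behavior_row("t1", "Cort/Veh", "W5", "open_arm_entries", s2),
        behavior_row("t1", "Cort/Veh", "W5", "latency_to_feed", 2 * s2),
        behavior_row("t1", "Cort/Veh", "W5", "grooming_duration", -s2),
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def random_psm_rows():
    """50 randomized peptide rows spanning both sides of every filter
    threshold, with multi-protein mappings."""
    rng = np.random.default_rng(42)
    rows = []
    proteins = [f"Q{i:02d}" for i in range(12)]
    for i in range(50):
        pep = f"pep{i:02d}"
        e = float(10 ** rng.uniform(-5, 0))  # spans the 0.01 cut
        k = int(rng.integers(1, 4))
        prots = frozenset(rng.choice(proteins, size=k, replace=False))
        rows.append((pep, e, prots))
    return rows


def psm_rows_to_frame(rows, n_samples=2, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for pep, e, prots in rows:
        for j in range(n_samples):
            recs.append(
                {
                    "peptide": pep,
                    "evalue": e,
                    "proteins": ";".join(sorted(prots)),
                    "sample": f"s{j + 1}",
                    "spectra": int(rng.poisson(4)),
                }
            )
    return pd.DataFrame(recs)
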