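import numpy as np
import pandas as pd
import pytest

from gpcrscreen import PipelineConfig, SimTruth, run_pipeline


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One default-configuration pipeline run (seed 0), shared across tests."""
    out = tmp_path_factory.mktemp("default_run")
    report = run_pipeline(PipelineConfig(), out)
    truth = SimTruth.from_dir(out)
    return report, truth, out


def make_echo_cohort(seed: int = 7, n: int = 5) -> pd.DataFrame:
    """Synthetic echo cohort with pressure-overload-like shifts.

    SHAM animals have normal rat values; TAC animals have dilated volumes,
    reduced systolic function and thickened walls.  Used as the seeded
    fixture for the group-comparison tests.
    """
    rng = np.random.default_rng(seed)
    profiles = {
        "SHAM": dict(hr=(400, 20), edv=(500, 30), esv=(180, 20), edd=(8.0, 0.3),
                     esd=(4.5, 0.3), aw=(1.6, 0.1), pw=(1.6, 0.1)),
        "TAC": dict(hr=(380, 20), edv=(650, 40), esv=(400, 40), edd=(9.0, 0.3),
                    esd=(6.5, 0.4), aw=(2.2, 0.15), pw=(2.2, 0.15)),
    }
    rows = []
    for grp, p in profiles.items():
        for i in range(n):
            rows.append(
                dict(animal=f"{grp.lower()}_{i + 1}", group=grp,
                     heart_rate=rng.normal(*p["hr"]), LVEDV=rng.normal(*p["edv"]),
                     LVESV=rng.normal(*p["esv"]), LVEDD=rng.normal(*p["edd"]),
                     LVESD=rng.normal(*p["esd"]), LVAWTd=rng.normal(*p["aw"]),
                     LVPWTd=rng.normal(*p["pw"]))
            )
    return pd.DataFrame(rows)
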