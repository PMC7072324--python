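"""Shared fixtures: synthetic study inputs with known ground truth."""

from __future__ import annotations

import pytest

from fretscreen import screening as sc
from fretscreen import synthetic_data as sd

# Published component ledger for the five representative complex models
# (binding free energy and its parts, kJ/mol; D_DA in nm).
LEDGER_ROWS = [
    # model_id, D_DA, dG_nonpol, dE_MM, minus_TdS, dG_pol, dG_B (3 s.f.)
    ("Model 1", 4.2, -34.0, 2.74e4, 536.0, -6.89e4, -4.10e4),
    ("Model 2", 4.1, -33.0, 2.73e4, 535.0, -4.89e4, -2.11e4),
    ("Model 3", 3.9, -38.0, 2.76e4, 537.0, -8.14e4, -5.33e4),
    ("Model 4", 3.8, -35.0, 2.78e4, 541.0, -7.66e4, -4.83e4),
    ("Model 5", 4.2, -31.0, 2.76e4, 543.0, -5.90e4, -3.09e4),
]


@pytest.fixture(scope="session")
def planted_ensemble():
    """Default 50-pose ensemble: 16 in-window poses in 5 planted clusters."""
    models, sites, manifest = sd.gen_pose_ensemble(sd.PoseEnsembleSpec(), seed=20)
    return sc.PoseEnsemble(models=models, sites=sites), manifest


@pytest.fixture(scope="session")
def ledger_rows():
    return LEDGER_ROWS
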