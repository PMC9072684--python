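"""Shared fixtures: a synthetic reference and a small simulated library.

Everything is generated at test time from fixed seeds; no fixture data is
stored on disk.
"""

from __future__ import annotations

import pytest

from msrtk import pileup_engine as pe
from msrtk import synthetic_data as sd


@pytest.fixture(scope="session")
def cfg() -> sd.SimConfig:
    return sd.SimConfig()


@pytest.fixture(scope="session")
def ref(cfg):
    """Default 17-gene synthetic tRNA reference."""
    return sd.make_reference(cfg, seed=1)


@pytest.fixture(scope="session")
def small_library(ref, cfg, tmp_path_factory):
    """One simulated sample at modest depth, with its truth and pileup."""
    out = tmp_path_factory.mktemp("lib")
    small = sd.SimConfig(depth_per_gene=1000)
    truth = sd.simulate_trna_library(ref, small, out, seed=7, samples={"S1": {}})
    mat = pe.build_pileup(out / "S1.sam", ref)
    return {"dir": out, "truth": truth, "pileup": mat, "cfg": small}
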