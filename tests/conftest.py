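"""Shared fixtures: germline set, small simulated benchmarks, toy repertoires."""

import numpy as np
import pytest

from bcrp.io import load_default_germline
from bcrp.records import ChainRecord, PairedCell, Repertoire
from bcrp.simulate import SimulationConfig, simulate_benchmark


@pytest.fixture(scope="session")
def germline():
    return load_default_germline()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_benchmark():
    """A small seeded benchmark with chain-mixed noise, shared across tests."""
    cfg = SimulationConfig(
        n_families=4, n_noise=150, n_chain_mixed=40, n_rounds=4, rng_seed=7
    )
    repertoire, truth = simulate_benchmark(cfg)
    return cfg, repertoire, truth


def make_heavy(sid, junction_aa, v="IGHV1-1", j="IGHJ1", cell_id="", **kw):
    return ChainRecord(
        sequence_id=sid, locus="IGH", v_call=v, j_call=j,
        junction_aa=junction_aa, cell_id=cell_id or sid, **kw,
    )


def make_light(sid, junction_aa, v="IGKV1-1", j="IGKJ1", locus="IGK", cell_id="", **kw):
    return ChainRecord(
        sequence_id=sid, locus=locus, v_call=v, j_call=j,
        junction_aa=junction_aa, cell_id=cell_id or sid, **kw,
    )


def make_cell(cid, h_junction, l_junction, lv="IGKV1-1", lj="IGKJ1",
              locus="IGK", hv="IGHV1-1", hj="IGHJ1", **kw):
    heavy = make_heavy(f"{cid}_H", h_junction, v=hv, j=hj, cell_id=cid, **kw)
    light = make_light(f"{cid}_L", l_junction, v=lv, j=lj, locus=locus, cell_id=cid, **kw)
    return PairedCell(cid, heavy, light)


@pytest.fixture()
def chain_mixed_repertoire():
    """One heavy-homogeneous cluster whose light chains split 4 vs 2."""
    cells = [
        make_cell(f"c{i}", "CARDYWGQGW", "CQQSYSTPW",
                  lv="IGKV1-1" if i < 4 else "IGLV2-1",
                  lj="IGKJ1" if i < 4 else "IGLJ2",
                  locus="IGK" if i < 4 else "IGL")
        for i in range(6)
    ]
    return Repertoire("mixfix", cells=cells)
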