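"""Shared fixtures: motif catalogue, synthetic NPS inserts, small manifests."""

from __future__ import annotations

import numpy as np
import pytest

import pioneerseq as ps


@pytest.fixture(scope="session")
def motifs():
    return ps.default_motifs()


@pytest.fixture(scope="session")
def demo_nps(motifs):
    """Three scrubbed synthetic 191-nt positioning inserts (601/5S/MMTV roles)."""
    return ps.make_demo_nps(seed=0, motifs=motifs)


@pytest.fixture(scope="session")
def nps601(demo_nps):
    return demo_nps[0]


@pytest.fixture(scope="session")
def small_manifest(nps601, motifs):
    """One NPS x two TFBS (298 tiled entries) + a few ITN-like entries."""
    by_id = {m.id: m for m in motifs}
    tiled = ps.tile_tfbs(nps601, by_id["Klf4-1"]) + ps.tile_tfbs(nps601, by_id["Sox2-1"])
    rng = np.random.default_rng(7)
    candidates = []
    for k in range(5):
        window = list("".join(rng.choice(list("ACGT"), size=191)))
        m = by_id["Oct4-1"]
        window[50 : 50 + len(m)] = m.site_seq
        candidates.append(
            ps.ITNCandidate(f"chr{k+1}", 1000 * k, 1000 * k + 191, "".join(window), score=0.9)
        )
    itns, _ = ps.select_itns(candidates, motifs)
    return ps.assemble_library(tiled, itns)


@pytest.fixture(scope="session")
def demo_manifest(motifs):
    """Reduced-scale demo library: 3 NPS x 4 factor-diverse TFBS + 10 ITNs."""
    return ps.simulate_demo_library(n_tfbs=4, seed=0, n_itn=10, motifs=motifs)


def make_read(seq: str, qual: int = 40, rid: str = "r") -> ps.SequencedRead:
    return ps.SequencedRead(rid, seq, (qual,) * len(seq))


@pytest.fixture(scope="session")
def read_factory():
    return make_read
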