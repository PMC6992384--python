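"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from ibsleak.ibs_engine import DetectorConfig
from ibsleak.simdata import SimConfig, make_population, sample_site_panel


@pytest.fixture(scope="session")
def world():
    """A mid-size simulated world with background haplotype sharing."""
    config = SimConfig(
        n_sites=3000,
        n_haplotypes=60,
        seed=3,
        length_cM=30.0,
        pair_rate=2.0,
        segment_scale_cM=4.0,
        n_share_pairs=240,
    )
    panel = sample_site_panel(config)
    kits, haps, ledger = make_population(panel, config)
    return {
        "config": config,
        "panel": panel,
        "kits": kits,
        "haps": haps,
        "ledger": ledger,
    }


@pytest.fixture(scope="session")
def small_panel():
    config = SimConfig(
        n_sites=200, n_haplotypes=4, seed=11, length_cM=10.0, pair_rate=0.0
    )
    return sample_site_panel(config)


@pytest.fixture()
def loose_detector():
    """Detector with filters effectively off (tiny length, 1 SNP)."""
    return DetectorConfig(min_len_cM=1e-9, min_snps=1)


@pytest.fixture(scope="session")
def probe_world():
    """Larger world tuned for probing: more sharing around a focal site."""
    from ibsleak.probing import InertSpec, make_inert_kit

    config = SimConfig(
        n_sites=6000, n_haplotypes=80, seed=9, length_cM=40.0,
        pair_rate=2.0, segment_scale_cM=5.0, n_share_pairs=500,
    )
    panel = sample_site_panel(config)
    kits, haps, ledger = make_population(panel, config)
    inert = make_inert_kit(panel, InertSpec(seed=21))
    focal = panel.n_sites // 2
    sources = haps[:30]
    source_ids = {h.hap_id for h in sources}
    carriers = {}
    for kit, (h1, h2) in zip(kits, zip(haps[::2], haps[1::2])):
        carriers[kit.kit_id] = any(
            rec.start_index <= focal <= rec.end_index and rec.hap_b in source_ids
            for h in (h1, h2)
            for rec in ledger.segments_for(h.hap_id)
        )
    return {
        "panel": panel, "kits": kits, "haps": haps, "inert": inert,
        "focal": focal, "sources": sources, "carriers": carriers,
    }
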