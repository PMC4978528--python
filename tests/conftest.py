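import itertools

import numpy as np
import pytest

import stemsplice as ss


def make_event(
    event_id="ev1",
    event_type=ss.EventType.EX_SINGLE,
    alt_length=81,
    inclusion=("j_C1A", "j_AC2"),
    exclusion=("j_C1C2",),
    strand="+",
):
    return ss.ASEvent(
        event_id=event_id,
        event_type=event_type,
        gene_id="g1",
        scaffold="scf1",
        strand=strand,
        alt_spans=((1000, 1000 + alt_length - 1),),
        alt_length=alt_length,
        inclusion_junctions=tuple(inclusion),
        exclusion_junctions=tuple(exclusion),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared by read-only tests."""
    cfg = ss.SimulationConfig(seed=11, n_events=300, n_differential=40)
    events, truth = ss.simulate_events(cfg)
    manifest = ss.make_manifest(cfg)
    counts = ss.simulate_counts(events, truth, manifest, cfg)
    table = ss.build_inclusion_table(events, counts, manifest)
    return cfg, events, truth, manifest, counts, table


@pytest.fixture(scope="session")
def gcuugc_library():
    """Synthetic 7-mer Z-score table whose top decile is anchored on GCUUGC."""
    rng = np.random.default_rng(99)
    kmers = ["".join(p) for p in itertools.product("ACGU", repeat=7)]
    return {
        "RBP_GCUUGC": {
            k: (10.0 + rng.random() if "GCUUGC" in k else float(rng.normal()))
            for k in kmers
        }
    }
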