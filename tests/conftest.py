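from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from konet import (
    AbundanceTable,
    AnnotationProfile,
    AnnotationRecord,
    Reaction,
)

settings.register_profile(
    "konet",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("konet")


def make_table(counts_by_sample: dict[str, dict[str, float]], state_labels=None):
    """Build an AbundanceTable from {sample: {ko: count}} dicts."""
    sample_ids = list(counts_by_sample)
    ko_ids = sorted({k for row in counts_by_sample.values() for k in row})
    counts = np.array(
        [[counts_by_sample[s].get(k, 0.0) for k in ko_ids] for s in sample_ids]
    )
    return AbundanceTable.from_counts(sample_ids, ko_ids, counts, state_labels)


def random_profile(rng, sample_id="s", n_reads=40, n_kos=8):
    """A random annotation profile mixing plain, multi-KO and tied reads."""
    kos = [f"K{i:05d}" for i in range(1, n_kos + 1)]
    records = []
    n_assigned = 0
    for i in range(n_reads):
        read_id = f"{sample_id}_r{i:04d}"
        a, b = (str(x) for x in rng.choice(kos, size=2))
        mant, expo = int(rng.integers(1, 10)), int(rng.integers(5, 40))
        e = float(f"{mant}e-{expo}")
        worse = float(f"{mant}e-{expo - 3}")
        u = rng.random()
        if u < 0.2 and a != b:
            records.append(AnnotationRecord(read_id, f"ref_{a}", e, (a,)))
            records.append(AnnotationRecord(read_id, f"ref_{b}", e, (b,)))
        elif u < 0.4 and a != b:
            records.append(AnnotationRecord(read_id, f"ref_{a}_{b}", e, (a, b)))
        elif u < 0.5:
            # a best hit plus a strictly worse hit that must be ignored
            records.append(AnnotationRecord(read_id, f"ref_{a}", e, (a,)))
            records.append(AnnotationRecord(read_id, f"worse_{b}", worse, (b,)))
        else:
            records.append(AnnotationRecord(read_id, f"ref_{a}", e, (a,)))
        n_assigned += 1
    return AnnotationProfile(sample_id=sample_id, records=records), n_assigned


@pytest.fixture
def chain_reactions():
    """K1 -C_B-> K2 -C_C-> K3 linear chain."""
    return [
        Reaction("R1", frozenset({"K1"}), frozenset({"C_A"}), frozenset({"C_B"})),
        Reaction("R2", frozenset({"K2"}), frozenset({"C_B"}), frozenset({"C_C"})),
        Reaction("R3", frozenset({"K3"}), frozenset({"C_C"}), frozenset({"C_D"})),
    ]
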