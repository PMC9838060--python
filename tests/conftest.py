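import numpy as np
import pytest

from iterquant import synth
from iterquant.amplicon import AmpliconTarget


def noise_free_models():
    return {
        k: synth.ChannelModel(m.foreground_mean, m.foreground_sd, m.background, 0.0)
        for k, m in synth.DEFAULT_CHANNEL_MODELS.items()
    }


@pytest.fixture
def wheat_config():
    """One sample well + one control well, noise-free, 50 cells + 10 debris."""
    return synth.SimulationConfig(
        wells={
            "A1": synth.WellCondition(n_cells=50, transfection_rate=0.6, editing_rate=0.4),
            "A2": synth.WellCondition(control=True, n_cells=50),
        },
        fields_per_well=1,
        debris_count=10,
        channel_models=noise_free_models(),
        rng_seed=11,
    )


@pytest.fixture
def wheat_field(wheat_config):
    stack, truth = synth.simulate_field(wheat_config, "A1", 0)
    return wheat_config, stack, truth


@pytest.fixture
def cas12a_target():
    amplicon = "GATTACAGGA" + "TTTC" + "TCAGTACGATGCAAGGTCATCGA" + "ACGGATTGCCAGT"
    return AmpliconTarget(
        target_id="TS1",
        amplicon=amplicon,
        protospacer="TCAGTACGATGCAAGGTCATCGA",
        strand="+",
        nuclease="Cas12a",
    )


@pytest.fixture
def cas9_target():
    spacer = "GACGTTACCGGATCTAGCAA"
    amplicon = "CCATGAACTT" + spacer + "TGGAGGATCCAGTTACGGA"
    return AmpliconTarget(
        target_id="cas9_t", amplicon=amplicon, protospacer=spacer, nuclease="Cas9"
    )


def centroid_match(truth_cells, records, tol=15.0):
    """Greedy nearest matching of truth cells to records; returns n matched."""
    used = set()
    matched = 0
    for t in truth_cells:
        best = None
        for i, r in enumerate(records):
            if i in used:
                continue
            d = np.hypot(r.centroid[0] - t.y, r.centroid[1] - t.x)
            if d < tol and (best is None or d < best[0]):
                best = (d, i)
        if best is not None:
            used.add(best[1])
            matched += 1
    return matched


def detection_f1(truth_cells, records, tol=15.0):
    tp = centroid_match(truth_cells, records, tol)
    if not records or not truth_cells:
        return 0.0
    precision = tp / len(records)
    recall = tp / len(truth_cells)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
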