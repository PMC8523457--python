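import math

import pytest

from strseqdb.catalog import default_catalog
from strseqdb.simulate import (
    AlleleSpec,
    HBModel,
    SimulationConfig,
    StutterModel,
    TotalReadsModel,
    build_scenario,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def concordance_scenario():
    """The deterministic 247-sample paired CE/MPS cohort with two injected
    single-allele drop-outs (built once per session; it is not small)."""
    return build_scenario("concordance_247")


def small_config(spectra: dict, n_samples: int, seed: int, **overrides) -> SimulationConfig:
    """Compact simulation config over a subset of loci (plus amelogenin)."""
    markers = sorted(spectra) + ["AMEL"]
    weights = {m: 1.0 / len(markers) for m in markers}
    weights["AMEL"] = 1.0 - sum(v for m, v in weights.items() if m != "AMEL")
    base = dict(
        n_samples=n_samples,
        freq_spectra=spectra,
        total_reads_model=TotalReadsModel(log_mean=math.log(50_000.0), log_sd=0.3),
        marker_weights=weights,
        hb_model={l: HBModel(alpha=25.0, beta=5.0) for l in spectra},
        stutter_model={l: StutterModel(intercept=-0.03, slope=0.01, sd=0.02) for l in spectra},
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def spectrum(*entries) -> list[AlleleSpec]:
    """Entries are (designation, freq[, seq_tag[, variants]]) tuples."""
    out = []
    for e in entries:
        out.append(AlleleSpec(
            designation=e[0], frequency=e[1],
            seq_tag=e[2] if len(e) > 2 else "",
            variants=list(e[3]) if len(e) > 3 else [],
        ))
    return out
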