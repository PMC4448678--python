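import logging

import pytest

from mtfusion import pipeline, simgen

logging.getLogger("mtfusion").setLevel(logging.WARNING)

SMALL_LENGTHS = {"chr1": 120_000, "chr2": 120_000}


def small_events():
    return [
        simgen.IntegrationSpec("chr1", 30_000, 2_000, 2_148, "+", (0, 0), name="E1"),
        simgen.IntegrationSpec("chr1", 70_000, 5_000, 6_000, "+", (1, 2), name="E2"),
        simgen.IntegrationSpec("chr2", 30_000, 15_400, 15_800, "-", (3, 0), name="E3"),
        simgen.IntegrationSpec("chr2", 70_000, 11_000, 11_600, "+", (0, 0),
                               insertion=("ACGT", ""), name="E4"),
        simgen.IntegrationSpec("chr1", 100_000, 8_000, 8_600, "+", (0, 0), germline=True, name="G1"),
    ]


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Small simulated tumor/normal cohort shared across tests (fast: Cmt=60)."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = simgen.ReadSimConfig(mean_depth=30, cmt=60)
    return simgen.simulate_cohort(out, seed=7, cfg=cfg, events=small_events(),
                                  genome_lengths=dict(SMALL_LENGTHS))


@pytest.fixture(scope="session")
def small_run(small_cohort, tmp_path_factory):
    """Full pipeline run over the small cohort."""
    out = tmp_path_factory.mktemp("run")
    cfg = {
        "simulate": {"enabled": False},
        "inputs": {
            "ref": str(small_cohort.paths["ref"]),
            "tumor": str(small_cohort.paths["tumor"]),
            "normal": str(small_cohort.paths["normal"]),
            "numts": str(small_cohort.paths["numts"]),
            "te": str(small_cohort.paths["te"]),
            "sv": str(small_cohort.paths["sv"]),
            "truth": str(small_cohort.paths["truth"]),
            "panel": [],
        },
        "stats": {"mh_draws": 500},
    }
    report = pipeline.run_pipeline(cfg, out_dir=out, seed=7)
    return {"report": report, "out": out, "cohort": small_cohort}
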