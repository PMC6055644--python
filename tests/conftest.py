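import pytest

from ch4pred import (CowRecord, SimConfig, SimulationTruth, generate_dataset,
                     records_to_frame)


def make_record(record_id="r1", group_id="g1", study_id="s1", region="EU",
                **numeric):
    defaults = dict(dmi=18.5, gei=347.0, ge_diet=18.7, cp=16.5, ee=3.5,
                    ndf=35.4, ash=7.3, my=27.0, mf=4.1, mp=3.4, bw=611.0,
                    ch4=369.0)
    defaults.update(numeric)
    return CowRecord(record_id=record_id, group_id=group_id,
                     study_id=study_id, region=region, **defaults)


@pytest.fixture
def mean_record():
    """A record at the pooled-database mean covariates."""
    return make_record()


@pytest.fixture(scope="session")
def sim_small():
    """Small simulated dataset: 3 groups x 3 studies x 10 cows."""
    cfg = SimConfig(n_groups=3, studies_per_group=3, cows_per_study=10,
                    truth=SimulationTruth(seed=42))
    records, truth = generate_dataset(cfg)
    return records, truth


@pytest.fixture(scope="session")
def sim_small_frame(sim_small):
    records, truth = sim_small
    return records_to_frame(records), truth
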