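import pytest

from pampakit.plate import ConcentrationRecord, SandwichGeometry


@pytest.fixture(scope="session")
def geometry() -> SandwichGeometry:
    return SandwichGeometry()


def make_record(
    cd0: float = 1.0,
    cd_t: float = 0.8,
    ca_t: float = 0.1,
    t: float = 57600.0,
    name: str = "drug",
    lipid: str = "C8",
) -> ConcentrationRecord:
    return ConcentrationRecord(
        compound_name=name,
        lipid_label=lipid,
        donor_pH=7.4,
        acceptor_pH=7.4,
        incubation_time_s=t,
        donor_conc_initial=cd0,
        donor_conc_final=cd_t,
        acceptor_conc_final=ca_t,
    )
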