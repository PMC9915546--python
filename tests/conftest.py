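import pytest

from vegrisk.data_model import METALS, PairedDataset, SoilSample, VegetableSample
from vegrisk.defaults import default_references, default_scenarios
from vegrisk.synthetic import GeneratorConfig, generate_dataset


def make_soil(sample_id="S001", ph=5.8, **metal_overrides):
    metals = {"Cd": 22.0, "Cr": 150.0, "Cu": 52.0, "Pb": 115.0, "V": 560.0,
              "Zn": 450.0}
    metals.update(metal_overrides)
    return SoilSample(
        sample_id=sample_id, ph=ph, som=27.0, dcb_fe=1.9, dcb_al=0.8,
        avail_n=59.0, avail_p=0.04, avail_k=80.0, metals=metals,
    )


def make_veg(sample_id="V001", soil_id="S001", species="pak choi",
             **metal_overrides):
    metals = {"Cd": 0.3, "Cr": 0.03, "Cu": 0.5, "Pb": 0.25, "V": 0.4,
              "Zn": 6.0}
    metals.update(metal_overrides)
    return VegetableSample(
        sample_id=sample_id, species=species, soil_id=soil_id, metals=metals
    )


@pytest.fixture(scope="session")
def references():
    return default_references()


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()


@pytest.fixture(scope="session")
def default_dataset():
    """The calibrated 51-site synthetic dataset at a fixed seed."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture
def tiny_dataset():
    soils = (make_soil("S001"), make_soil("S002", ph=6.5, Cd=10.0))
    vegs = (make_veg("V001", "S001"), make_veg("V002", "S002", Cd=0.1))
    return PairedDataset(soils=soils, vegetables=vegs)


__all__ = ["METALS", "make_soil", "make_veg"]
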