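import pytest

from herbnet.io_model import CompoundRecord, DescriptorBlock


@pytest.fixture
def apigenin_block() -> DescriptorBlock:
    """Apigenin's SwissADME-style descriptors: passes all five rule sets."""
    return DescriptorBlock(
        mw=270.24,
        mlogp=0.52,
        wlogp=2.58,
        xlogp=1.7,
        hba=5,
        hbd=3,
        rotb=1,
        tpsa=90.9,
        molar_refractivity=73.99,
        heavy_atoms=20,
        carbons=15,
        heteroatoms=5,
        rings=3,
    )


@pytest.fixture
def glycoside_block() -> DescriptorBlock:
    """Heavy glycoside-like descriptors: fails Lipinski, Ghose and Muegge."""
    return DescriptorBlock(
        mw=900,
        mlogp=-2.5,
        wlogp=-1.0,
        xlogp=-3.0,
        hba=18,
        hbd=11,
        rotb=6,
        tpsa=120,
        molar_refractivity=200,
        heavy_atoms=60,
        carbons=33,
        heteroatoms=25,
        rings=6,
    )


def make_compound(cid: str, ob: float, block: DescriptorBlock | None = None) -> CompoundRecord:
    return CompoundRecord(
        compound_id=cid,
        name=f"compound {cid}",
        ob_score=ob,
        descriptors=block or DescriptorBlock(),
    )
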