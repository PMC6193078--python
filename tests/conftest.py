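import pandas as pd
import pytest

from allodyn import SynthSpec, gvh_nssnps, synth_vcf_pair
from allodyn.reference import load_dual_presentation_example


@pytest.fixture(scope="session")
def spec():
    return SynthSpec(n_sites=100, gvh_fraction=0.3)


@pytest.fixture(scope="session")
def vcf_pair(spec, tmp_path_factory):
    """A deterministic synthetic donor/recipient VCF pair with truth."""
    outdir = tmp_path_factory.mktemp("vcfs")
    return synth_vcf_pair(spec, outdir, seed=11, drp_id="DRPTEST")


@pytest.fixture(scope="session")
def recovered_snps(vcf_pair):
    return gvh_nssnps(vcf_pair["donor"], vcf_pair["recipient"],
                      drp_id="DRPTEST")


@pytest.fixture(scope="session")
def truth(vcf_pair):
    return pd.read_csv(vcf_pair["truth"], sep="\t")


@pytest.fixture(scope="session")
def dual_example():
    """Bundled 20-gene dual-presentation affinity table."""
    df = load_dual_presentation_example()
    return (df[df["hla_class"] == "I"].reset_index(drop=True),
            df[df["hla_class"] == "II"].reset_index(drop=True))
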