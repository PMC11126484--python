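import numpy as np
import pandas as pd
import pytest

from nsip.community_summary import ZotuTable
from nsip.sip_quant import FractionProfile
from nsip.synthetic_data import GradientProtocol, TaxonSpec


@pytest.fixture
def noiseless_protocol() -> GradientProtocol:
    return GradientProtocol(qpcr_noise_sigma=0.0, detection_floor=0.0)


@pytest.fixture
def labeled_taxon() -> TaxonSpec:
    return TaxonSpec("aob_sim", total_copies=1e7, gc=0.5, atom15n=1.0)


@pytest.fixture
def unlabeled_taxon() -> TaxonSpec:
    return TaxonSpec("aob_sim", total_copies=1e7, gc=0.5, atom15n=0.0)


def make_profile(copies, gene="AOB", treatment="15N", replicate="1"):
    """16-fraction profile on the default linear grid (fraction 1 heaviest)."""
    n = len(copies)
    edges = np.linspace(1.780, 1.660, n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FractionProfile(
        gene=gene,
        treatment=treatment,
        replicate=replicate,
        fraction_index=tuple(range(1, n + 1)),
        buoyant_density=tuple(centers),
        copies=tuple(float(c) for c in copies),
    )


@pytest.fixture
def small_zotu_table() -> ZotuTable:
    counts = pd.DataFrame(
        {
            "hf_a": [40, 30, 20, 10, 0],
            "hf_b": [44, 26, 20, 10, 0],
            "light_a": [5, 5, 30, 10, 50],
            "light_b": [5, 5, 30, 10, 50],
        },
        index=pd.Index(["Zotu1", "Zotu2", "Zotu3", "Zotu4", "Zotu5"], name="zotu"),
    )
    metadata = pd.DataFrame(
        {
            "soil": ["acidic"] * 4,
            "treatment": ["15N-urea", "15N-urea", "CK", "CK"],
            "fraction_class": ["HF", "HF", "light", "light"],
        },
        index=pd.Index(["hf_a", "hf_b", "light_a", "light_b"], name="sample"),
    )
    taxonomy = pd.DataFrame(
        {
            "gene": ["AOA"] * 5,
            "clade": ["NS-Gamma", "NS-Alpha", "NS-Alpha", "NS-Zeta", "NT-Alpha"],
            "genus": ["g1", "g1", "g2", "g2", "g3"],
        },
        index=counts.index,
    )
    return ZotuTable(counts=counts, metadata=metadata, taxonomy=taxonomy)
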