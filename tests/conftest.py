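from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mrkit.types import HarmonizedSet, OutcomeDataset, VariantAssociation

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def random_harmonized(rng: np.random.Generator, j: int = 10, theta: float = 0.2) -> HarmonizedSet:
    """A random harmonized set with plausible scales and nonzero beta_x."""
    bx = rng.uniform(0.08, 0.6, j) * rng.choice([-1.0, 1.0], j)
    sx = rng.uniform(0.01, 0.05, j)
    sy = rng.uniform(0.01, 0.08, j)
    by = theta * bx + sy * rng.standard_normal(j)
    return HarmonizedSet(
        rsids=[f"rs{i}" for i in range(j)],
        beta_x=bx, se_x=sx, beta_y=by, se_y=sy,
        eaf_x=rng.uniform(0.1, 0.9, j), eaf_y=rng.uniform(0.1, 0.9, j),
    )


def make_variant(rsid="rs1", ea="G", oa="A", beta=0.1, se=0.02, p=1e-8,
                 eaf=0.3, chrom="1", pos=1000, n=10000) -> VariantAssociation:
    return VariantAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pvalue=p, eaf=eaf, chrom=chrom, pos=pos, n=n,
    )


def outcome_from(label: str, records) -> OutcomeDataset:
    return OutcomeDataset.from_records(label, records)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240810)


@pytest.fixture(scope="session")
def chb_instruments():
    from mrkit.io import load_chb_instruments

    return load_chb_instruments()


@pytest.fixture(scope="session")
def chb_study():
    from mrkit.simulate import paper_like_study

    return paper_like_study(seed=7, theta=0.0)
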