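import numpy as np
import pytest

import deldeck as dd
from deldeck.design import BuildingBlock, DesignManifest, generate_codebook


def make_manifest(
    n_a: int,
    n_b: int,
    stereo=("R", "S"),
    seed: int = 11,
    code_length: int = 6,
    d_min: int = 3,
    with_properties: bool = True,
) -> DesignManifest:
    """Small synthetic manifest with cycling chemistry classes."""
    rng = np.random.default_rng(seed)
    a_classes = ["primary-amine", "secondary-amine", "heteroaromatic-amine"]
    blocks_a, blocks_b = [], []
    for i in range(n_a):
        cls = "ammonia-control" if i == n_a - 1 and n_a > 1 else a_classes[i % 3]
        props = (
            dict(
                mass=round(float(rng.uniform(50, 200)), 2),
                hbd=int(rng.integers(0, 3)),
                hba=int(rng.integers(0, 4)),
                logp_contrib=round(float(rng.normal(0.8, 0.9)), 2),
            )
            if with_properties
            else {}
        )
        blocks_a.append(BuildingBlock(f"A{i + 1}", "A", cls, **props))
    for i in range(n_b):
        cls = "carboxylic-acid" if i % 4 else "alkyne"
        props = (
            dict(
                mass=round(float(rng.uniform(60, 250)), 2),
                hbd=int(rng.integers(0, 3)),
                hba=int(rng.integers(1, 5)),
                logp_contrib=round(float(rng.normal(1.0, 1.0)), 2),
            )
            if with_properties
            else {}
        )
        blocks_b.append(BuildingBlock(f"B{i + 1}", "B", cls, **props))
    return DesignManifest(
        blocks_a=blocks_a,
        blocks_b=blocks_b,
        codebook_a=generate_codebook(n_a, code_length, d_min, seed=seed, role="CodeA", prefix="A"),
        codebook_b=generate_codebook(n_b, code_length, d_min, seed=seed + 1, role="CodeB", prefix="B"),
        stereo_labels=list(stereo),
        scaffold_mass=231.2 if with_properties else None,
        d_min=d_min,
    )


@pytest.fixture(scope="session")
def small_manifest() -> DesignManifest:
    return make_manifest(6, 8)


@pytest.fixture(scope="session")
def ref_manifest() -> DesignManifest:
    """The published library shape: 2 stereoisomers x 300 A x 611 B."""
    return dd.reference_manifest(seed=0, with_properties=False)
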