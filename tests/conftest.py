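"""Shared fixtures: synthetic guide libraries and image geometry sampling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coldsplice import screen_counts as sc
from coldsplice import synthetic_data as sd


def random_guide_library(
    n_genes: int = 210, guides_per_gene: int = 4, n_non_targeting: int = 100, seed: int = 0
) -> sc.GuideLibrary:
    """A unique-sequence library with non-targeting controls first."""
    rng = np.random.default_rng(seed)
    n = n_genes * guides_per_gene + n_non_targeting
    seqs: set[str] = set()
    while len(seqs) < n:
        block = rng.choice(list("ACGT"), size=(n - len(seqs), 20))
        seqs.update("".join(row) for row in block)
    seqs_list = sorted(seqs)[:n]
    genes = [sc.NON_TARGETING] * n_non_targeting + [
        f"GENE{i // guides_per_gene}" for i in range(n_genes * guides_per_gene)
    ]
    return sc.GuideLibrary(
        pd.DataFrame(
            {
                "guide_id": [f"g{i}" for i in range(n)],
                "gene": genes,
                "sequence": seqs_list,
            }
        )
    )


@pytest.fixture(scope="session")
def guide_library() -> sc.GuideLibrary:
    return random_guide_library()


@pytest.fixture(scope="session")
def small_guide_library() -> sc.GuideLibrary:
    return random_guide_library(n_genes=10, guides_per_gene=4, n_non_targeting=12, seed=3)


def sample_cell_geometry(rng: np.random.Generator) -> tuple[sd.CellImageSimParams, dict]:
    """Random single-cell geometry with reporter SNR 10; returns params and true means."""
    soma_r = rng.uniform(24, 38)
    nuc_r = rng.uniform(10, 0.45 * soma_r + 5)
    off = rng.uniform(0, soma_r - nuc_r - 2)
    ang = rng.uniform(0, 2 * np.pi)
    cyto = rng.uniform(80, 150)
    nuc = cyto * rng.uniform(1.5, 2.5)
    params = sd.CellImageSimParams(
        soma_radius=soma_r,
        nucleus_radius=nuc_r,
        nucleus_center=(48 + off * np.sin(ang), 48 + off * np.cos(ang)),
        channel_means={
            "nuclear_stain": {"nucleus": rng.uniform(100, 200), "cytoplasm": 0.0},
            "reporter": {"nucleus": nuc, "cytoplasm": cyto},
        },
        background=10.0,
        gradient=(2.0, 2.0),
        noise_sd=cyto / 10,  # SNR 10 on the dimmest compartment
        seed=int(rng.integers(2**31)),
    )
    return params, {"cytoplasm": cyto, "nucleus": nuc}
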