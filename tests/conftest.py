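import numpy as np
import pandas as pd
import pytest

from wfmr import DosageMatrix, SNPPanel, simulate_families, simulate_panel


@pytest.fixture(scope="session")
def demo_panel():
    """60-variant panel with the default class mix."""
    return simulate_panel(60, seed=11)


@pytest.fixture(scope="session")
def m_only_panel():
    """Maternal-specific lead-SNP panel (29 variants, all w_fetal = 0)."""
    return simulate_panel(29, class_mix={"M_ONLY": 1.0}, seed=5)


@pytest.fixture(scope="session")
def trio_cohort(demo_panel):
    """800 families with two children each (sibling analyses possible)."""
    return simulate_families(demo_panel, 800, seed=3, n_children=2)


@pytest.fixture()
def tiny_panel():
    """Hand-built 3-variant panel with unit weights for arithmetic checks."""
    return SNPPanel(
        pd.DataFrame(
            {
                "variant_id": ["v1", "v2", "v3"],
                "effect_allele": ["A", "C", "G"],
                "eaf": [0.2, 0.4, 0.3],
                "effect_class": ["M_ONLY", "M_ONLY", "M_ONLY"],
                "w_maternal": [1.0, 1.0, 1.0],
                "w_fetal": [0.0, 0.0, 0.0],
            }
        )
    )


@pytest.fixture()
def tiny_dosages():
    return DosageMatrix(
        pd.DataFrame(
            [[2.0, 1.0, 0.0], [2.0, 2.0, 2.0], [0.0, 1.0, 1.0]],
            index=pd.Index(["i1", "i2", "i3"], name="individual_id"),
            columns=["v1", "v2", "v3"],
        )
    )


def pair_frame(cohort, scores, pheno, score, parent_role="MOTHER", outcome="disease"):
    """Assemble the one-row-per-pair analysis table used by the MR triplet."""
    pairs = cohort.parent_child_pairs(parent_role)
    return pd.DataFrame(
        {
            "pgs_parent": scores.loc[pairs["parent_id"], score].to_numpy(),
            "pgs_child": scores.loc[pairs["child_id"], score].to_numpy(),
            "outcome": pheno.table.loc[pairs["child_id"], outcome].to_numpy(),
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
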