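import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import svrdeconv as sd

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=40,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> sd.SyntheticSpec:
    """Small, fast compendium: 4 types x 4 replicates, 400 genes."""
    return sd.SyntheticSpec(
        n_cell_types=4,
        n_replicates_per_type=4,
        n_genes=400,
        n_markers_per_type=50,
        marker_effect=4.0,
        noise_sd=0.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_reference(small_spec):
    return sd.generate_reference(small_spec)


@pytest.fixture(scope="session")
def noiseless_signature():
    """Well-conditioned 9-type signature from a noise-free compendium.

    With zero replicate noise every scan submatrix is rank-deficient
    (kappa = inf throughout the grid), so the condition scan cannot
    discriminate; the signature is taken over all significant (marker)
    genes instead.
    """
    spec = sd.SyntheticSpec(seed=2, noise_sd=0.0)
    expr, ann, _ = sd.generate_reference(spec)
    ranked = sd.anova_rank(expr, ann)
    selected = ranked.index[ranked["significant"]]
    return sd.summarize_by_cell_type(expr.loc[selected], ann)


@pytest.fixture
def tiny_expr() -> pd.DataFrame:
    return pd.DataFrame(
        [[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]],
        index=pd.Index(["g1", "g2", "g3"], name="feature_id"),
        columns=["s1", "s2"],
    )


@pytest.fixture
def two_group_expr():
    """6 samples in 2 cell types with one clean between-group contrast."""
    expr = pd.DataFrame(
        {
            "a1": [1.0, 5.0],
            "a2": [2.0, 5.1],
            "a3": [3.0, 4.9],
            "b1": [4.0, 5.0],
            "b2": [5.0, 5.2],
            "b3": [6.0, 4.8],
        },
        index=pd.Index(["diff", "flat"], name="feature_id"),
    )
    ann = pd.DataFrame(
        {"cell_type": ["A", "A", "A", "B", "B", "B"]},
        index=pd.Index(expr.columns, name="sample_id"),
    )
    return expr, ann


def brute_force_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Independent one-way fixed-effects ANOVA from group/grand means."""
    from scipy import stats

    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_values) - len(groups)
    F = (ssb / df_b) / (ssw / df_w)
    return F, float(stats.f.sf(F, df_b, df_w))
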