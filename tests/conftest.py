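import numpy as np
import pytest

from selset import fixtures, head_model


@pytest.fixture(scope="session")
def montage():
    return head_model.standard_montage()


@pytest.fixture(scope="session")
def dipoles():
    return fixtures.default_dipoles()


@pytest.fixture(scope="session")
def worked_example_sig():
    """Significance table from the packaged worked-example grid at the
    0.80 uV threshold."""
    from selset import contrasts

    return contrasts.classify_cells(
        fixtures.enhancement_differences(),
        0.80,
        fixtures.enhancement_polarity(),
        electrodes=list(head_model.DEFAULT_LABELS),
    )


def anova_oracle(y: np.ndarray) -> dict[str, float]:
    """Brute-force sequential projection-matrix sums of squares.

    ``y`` has shape (groups, units, A, C) with units nested in groups.
    Each term's SS is the increase in explained SS when its indicator
    block joins the hierarchical design; on balanced data this matches the
    classical decomposition.  Kept deliberately independent of the package
    implementation.
    """
    g_n, u_n, a_n, c_n = y.shape
    flat = y.reshape(-1)
    obs = [
        (g, u, a, c)
        for g in range(g_n)
        for u in range(u_n)
        for a in range(a_n)
        for c in range(c_n)
    ]

    def block(axes):
        combos: dict[tuple, int] = {}
        for o in obs:
            combos.setdefault(tuple(o[k] for k in axes), len(combos))
        mat = np.zeros((len(obs), len(combos)))
        for i, o in enumerate(obs):
            mat[i, combos[tuple(o[k] for k in axes)]] = 1.0
        return mat

    terms = [
        ((), "intercept"),
        ((0,), "bin"),
        ((0, 1), "subject(bin)"),
        ((2,), "electrode"),
        ((0, 2), "bin:electrode"),
        ((0, 1, 2), "electrode:subject(bin)"),
        ((3,), "condition"),
        ((0, 3), "bin:condition"),
        ((0, 1, 3), "condition:subject(bin)"),
        ((2, 3), "electrode:condition"),
        ((0, 2, 3), "bin:electrode:condition"),
        ((0, 1, 2, 3), "electrode:condition:subject(bin)"),
    ]
    design = np.empty((len(obs), 0))
    prev = 0.0
    out: dict[str, float] = {}
    for axes, name in terms:
        design = np.hstack([design, block(axes)])
        beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
        resid = flat - design @ beta
        explained = float(flat @ flat - resid @ resid)
        if name != "intercept":
            out[name] = explained - prev
        prev = explained
    return out
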