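import numpy as np
import pytest

from conformeq import NON_BINDING, FourStateModel, SyntheticConfig


@pytest.fixture
def kg548_model():
    """Four-state model with the fitted WT affinity and a non-binding SLIP state."""
    return FourStateModel(keq_apo=1.0, kd_wt=684.0, kd_slip=NON_BINDING)


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


def bisection_oracle(model, p_total, l_total, iters=200):
    """Independent brute-force solver: plain bisection on free ligand.

    Deliberately separate from the package solver (no brentq, its own
    back-substitution) so the two can disagree.
    """
    def species(l_free):
        keq = model.keq_apo
        kd_slip = getattr(model, "kd_slip", None)
        slip_binds = isinstance(kd_slip, (int, float)) and np.isfinite(kd_slip)
        # solve [SLIP_u] = s from protein balance: states in terms of s
        # WT_u = keq*s ; WT_b = keq*s*L/kd_wt ; SLIP_b = s*L/kd_slip
        coef = 1.0 + keq + keq * l_free / model.kd_wt
        if slip_binds:
            coef += l_free / kd_slip
        s = p_total / coef
        wt_u = keq * s
        wt_b = wt_u * l_free / model.kd_wt
        slip_b = s * l_free / kd_slip if slip_binds else 0.0
        return wt_u, wt_b, s, slip_b

    lo, hi = 0.0, l_total
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        _, wt_b, _, slip_b = species(mid)
        if mid + wt_b + slip_b > l_total:
            hi = mid
        else:
            lo = mid
    l_free = 0.5 * (lo + hi)
    return (*species(l_free), l_free)
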