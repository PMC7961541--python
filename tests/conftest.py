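"""Shared fixtures and independent scalar-loop oracles.

The reference implementations here are deliberately naive (nested
loops, explicit index arithmetic) so they are independent of the
vectorised implementations they check.
"""

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def ref_conv2d(x, w, b=None, stride=1, pad=0, dilation=1):
    """Brute-force 2-D cross-correlation, NCHW, scalar loops."""
    n, cin, h, wdt = x.shape
    cout, _, kh, kw = w.shape
    eh = dilation * (kh - 1) + 1
    ew = dilation * (kw - 1) + 1
    ho = (h + 2 * pad - eh) // stride + 1
    wo = (wdt + 2 * pad - ew) // stride + 1
    xp = np.zeros((n, cin, h + 2 * pad, wdt + 2 * pad), dtype=np.float64)
    xp[:, :, pad:pad + h, pad:pad + wdt] = x
    out = np.zeros((n, cout, ho, wo))
    for ni in range(n):
        for co in range(cout):
            for oh in range(ho):
                for ow in range(wo):
                    acc = 0.0
                    for ci in range(cin):
                        for ki in range(kh):
                            for kj in range(kw):
                                acc += (xp[ni, ci,
                                           oh * stride + ki * dilation,
                                           ow * stride + kj * dilation]
                                        * w[co, ci, ki, kj])
                    out[ni, co, oh, ow] = acc + (b[co] if b is not None else 0.0)
    return out


def numeric_grad(f, x, eps=1e-5):
    """Central finite-difference gradient of scalar f w.r.t. array x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat = x.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return g
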