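"""Optional numba-accelerated inner loops for the solver.

Everything here has a pure-numpy twin in :mod:`ribbonca.solver`; the JIT
versions are used when numba imports and compiles cleanly, otherwise the
solver silently falls back.  Results agree to rounding because the
arithmetic is identical.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def thomas_inplace(rhs, a, cp, inv):  # pragma: no cover - numba path
    """Solve the pre-factorized tridiagonal systems; rhs is (n, nlines)."""
    n, m = rhs.shape
    for j in range(m):
        rhs[0, j] *= inv[0, j]
    for i in range(1, n):
        for j in range(m):
            rhs[i, j] = (rhs[i, j] - a[i, j] * rhs[i - 1, j]) * inv[i, j]
    for i in range(n - 2, -1, -1):
        for j in range(m):
            rhs[i, j] -= cp[i, j] * rhs[i + 1, j]


@njit(cache=False)
def reaction_newton(c, bnd, bt, kon, koff, dt, out_c, out_bnd):  # pragma: no cover
    """Backward-Euler update of the local buffering network per voxel.

    ``bnd``/``bt`` are (nb, N); solves the conservation equation for the
    new free Ca2+ by safeguarded Newton iteration, then back-substitutes
    the bound-buffer closed forms.
    """
    nb, n = bnd.shape
    for j in range(n):
        total = c[j]
        for i in range(nb):
            total += bnd[i, j]
        cp = c[j]
        for _ in range(60):
            g = cp - total
            dg = 1.0
            for i in range(nb):
                denom = 1.0 + dt * (kon[i] * cp + koff[i])
                num = bnd[i, j] + dt * kon[i] * cp * bt[i, j]
                bn = num / denom
                g += bn
                dg += (dt * kon[i] * bt[i, j] - bn * dt * kon[i]) / denom
            step = g / dg
            cpn = cp - step
            if cpn < 0.0:
                cpn = 0.0
            elif cpn > total:
                cpn = total
            if abs(cpn - cp) < 1e-12 * (1.0 + total):
                cp = cpn
                break
            cp = cpn
        out_c[j] = cp
        for i in range(nb):
            denom = 1.0 + dt * (kon[i] * cp + koff[i])
            out_bnd[i, j] = (bnd[i, j] + dt * kon[i] * cp * bt[i, j]) / denom
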