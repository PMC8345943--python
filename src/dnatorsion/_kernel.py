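"""Numba-compiled RK4 stepping kernel.

Semantically identical to repeated :func:`dnatorsion.integration.rk4_step`
on :func:`dnatorsion.model.rhs`: same ψ₂ = φ₂ − π formulation of the pair
torques, same free-end torsional stencil, same stage weights.  Kept in its
own module so that the rest of the package imports cleanly when numba is
unavailable.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _accel(yp1, yp2, yv1, yv2, I1, I2, K1, K2, b1, b2, con1, con2, cx,
           F0, om, variant, ts, a1, a2):
    n = yp1.shape[0]
    drive = F0 * np.cos(om * ts)
    for i in range(n):
        if n == 1:
            tor1 = 0.0
            tor2 = 0.0
        elif i == 0:
            tor1 = K1[0] * (yp1[1] - yp1[0])
            tor2 = K2[0] * (yp2[1] - yp2[0])
        elif i == n - 1:
            tor1 = K1[i] * (yp1[i - 1] - yp1[i])
            tor2 = K2[i] * (yp2[i - 1] - yp2[i])
        else:
            tor1 = K1[i] * (yp1[i - 1] - 2.0 * yp1[i] + yp1[i + 1])
            tor2 = K2[i] * (yp2[i - 1] - 2.0 * yp2[i] + yp2[i + 1])
        psi2 = yp2[i] - np.pi
        sin_diff = np.sin(yp1[i] - psi2)  # = -sin(phi1 - phi2)
        if variant == 0:
            pair2 = -con1[i] * np.sin(psi2) + cx[i] * sin_diff
        else:
            pair2 = con2[i] * np.sin(psi2) - cx[i] * sin_diff
        a1[i] = (tor1 - con1[i] * np.sin(yp1[i]) + cx[i] * sin_diff
                 - b1[i] * yv1[i] + drive) / I1[i]
        a2[i] = (tor2 + pair2 - b2[i] * yv2[i] + drive) / I2[i]


@njit(cache=False)
def rk4_kernel(p1, p2, v1, v2, I1, I2, K1, K2, b1, b2, con1, con2, cx,
               F0, om, variant, t0, dt, nsteps, stride,
               mean1, mean2, rec_p1, rec_p2, rec_v1, rec_v2, store):
    n = p1.shape[0]
    a1 = np.empty(n); a2 = np.empty(n)
    yp1 = np.empty(n); yp2 = np.empty(n); yv1 = np.empty(n); yv2 = np.empty(n)
    # stage derivatives
    kp1 = np.empty(n); kp2 = np.empty(n); kv1 = np.empty(n); kv2 = np.empty(n)
    # accumulated weighted sums
    sp1 = np.empty(n); sp2 = np.empty(n); sv1 = np.empty(n); sv2 = np.empty(n)

    mean1[0] = p1.mean(); mean2[0] = p2.mean()
    if store:
        for i in range(n):
            rec_p1[0, i] = p1[i]; rec_p2[0, i] = p2[i]
            rec_v1[0, i] = v1[i]; rec_v2[0, i] = v2[i]
    ri = 1
    for step in range(nsteps):
        t = t0 + step * dt
        for stage in range(4):
            if stage == 0:
                ts = t
                for i in range(n):
                    yp1[i] = p1[i]; yp2[i] = p2[i]; yv1[i] = v1[i]; yv2[i] = v2[i]
            elif stage == 3:
                ts = t + dt
                for i in range(n):
                    yp1[i] = p1[i] + dt * kp1[i]; yp2[i] = p2[i] + dt * kp2[i]
                    yv1[i] = v1[i] + dt * kv1[i]; yv2[i] = v2[i] + dt * kv2[i]
            else:
                ts = t + 0.5 * dt
                h = 0.5 * dt
                for i in range(n):
                    yp1[i] = p1[i] + h * kp1[i]; yp2[i] = p2[i] + h * kp2[i]
                    yv1[i] = v1[i] + h * kv1[i]; yv2[i] = v2[i] + h * kv2[i]
            _accel(yp1, yp2, yv1, yv2, I1, I2, K1, K2, b1, b2, con1, con2, cx,
                   F0, om, variant, ts, a1, a2)
            w = 1.0 if (stage == 0 or stage == 3) else 2.0
            for i in range(n):
                kp1[i] = yv1[i]; kp2[i] = yv2[i]; kv1[i] = a1[i]; kv2[i] = a2[i]
            if stage == 0:
                for i in range(n):
                    sp1[i] = kp1[i]; sp2[i] = kp2[i]; sv1[i] = kv1[i]; sv2[i] = kv2[i]
            else:
                for i in range(n):
                    sp1[i] += w * kp1[i]; sp2[i] += w * kp2[i]
                    sv1[i] += w * kv1[i]; sv2[i] += w * kv2[i]
        h6 = dt / 6.0
        for i in range(n):
            p1[i] += h6 * sp1[i]; p2[i] += h6 * sp2[i]
            v1[i] += h6 * sv1[i]; v2[i] += h6 * sv2[i]
        if (step + 1) % stride == 0:
            ok = True
            for i in range(n):
                if not (np.isfinite(p1[i]) and np.isfinite(p2[i])
                        and np.isfinite(v1[i]) and np.isfinite(v2[i])):
                    ok = False
            if not ok:
                return 1, step + 1
            mean1[ri] = p1.mean(); mean2[ri] = p2.mean()
            if store:
                for i in range(n):
                    rec_p1[ri, i] = p1[i]; rec_p2[ri, i] = p2[i]
                    rec_v1[ri, i] = v1[i]; rec_v2[ri, i] = v2[i]
            ri += 1
    return 0, nsteps
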